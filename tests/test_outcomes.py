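import numpy as np
import pandas as pd
import pytest

from ppmsprog.cohort import LongitudinalCohort
from ppmsprog.outcomes import (
    CDPDefinition,
    InvalidBaselineError,
    build_event_table,
    detect_cdp_edss,
    detect_cdp_percent,
    detect_cdp_sdmt,
    detect_confirmed_edss6,
    edss_required_increase,
    fit_cox,
    km_and_logrank,
)


class TestEdssCdp:
    @pytest.mark.parametrize(
        "times,values,event,time",
        [
            # baseline 4.0: 1-point band; worsening at m3 confirmed at m6
            ([0, 3, 6], [4.0, 5.0, 5.0], True, 3.0),
            # baseline 6.0: 0.5-point band
            ([0, 3, 6], [6.0, 6.5, 6.5], True, 3.0),
            # worsening not confirmed
            ([0, 3, 6], [4.0, 5.0, 4.0], False, 6.0),
            # sub-threshold change
            ([0, 3, 6], [4.0, 4.5, 4.5], False, 6.0),
            # candidate without any visit >= 3 months later cannot confirm
            ([0, 3, 4], [4.0, 4.0, 5.0], False, 4.0),
        ],
    )
    def test_rule_examples(self, times, values, event, time):
        out = detect_cdp_edss(times, values)
        assert out.event is event
        assert out.time_months == pytest.approx(time)

    def test_out_of_band_baselines_follow_convention_and_flag(self):
        step, flag = edss_required_increase(2.0)
        assert step == 1.0 and "below 3.0" in flag
        step, flag = edss_required_increase(7.0)
        assert step == 0.5 and "7.0" in flag
        step, flag = edss_required_increase(4.5)
        assert step == 1.0 and flag is None

    def test_single_visit_censored_with_warning(self):
        with pytest.warns(UserWarning, match="single-visit"):
            out = detect_cdp_edss([0.0], [4.0])
        assert not out.event

    def test_sustained_vs_lenient_confirmation(self):
        # dip below threshold before the confirmation visit voids the
        # candidate under the strict reading but not the lenient one
        times = [0, 1, 2, 5]
        values = [4.0, 5.0, 4.0, 5.0]
        assert not detect_cdp_edss(times, values, sustained=True).event
        lenient = detect_cdp_edss(times, values, sustained=False)
        assert lenient.event and lenient.time_months == 1.0


class TestPercentCdp:
    def test_exactly_20_percent_qualifies(self):
        out = detect_cdp_percent([0, 3, 6], [10.0, 12.0, 12.5])
        assert out.event and out.time_months == 3.0

    def test_below_threshold_censored(self):
        out = detect_cdp_percent([0, 3, 6], [10.0, 11.9, 11.9])
        assert not out.event and out.time_months == 6.0

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(InvalidBaselineError):
            detect_cdp_percent([0, 3], [0.0, 5.0])


class TestSdmtCdp:
    @pytest.mark.parametrize(
        "values,event",
        [
            ([40.0, 36.0, 36.0], True),    # -4 points
            ([20.0, 18.0, 18.0], True),    # -2 points but 10% of 20
            ([40.0, 38.0, 38.0], False),   # -2 points, < 3 and < 10%
        ],
    )
    def test_points_or_percent_branches(self, values, event):
        out = detect_cdp_sdmt([0, 3, 9], values)
        assert out.event is event
        if event:
            assert out.time_months == 3.0


class TestEdss6Milestone:
    def test_confirmed_milestone_on_onset_axis(self):
        res = detect_confirmed_edss6([0, 6, 9], [5.5, 6.0, 6.0],
                                     baseline_odd_years=5.0, age_onset_years=40.0)
        assert res["event"]
        assert res["time_years_from_onset"] == pytest.approx(5.5)
        assert res["age_at_event"] == pytest.approx(45.5)

    def test_never_reached_censored_at_last_visit(self):
        res = detect_confirmed_edss6([0, 6, 12], [4.0, 4.5, 5.0],
                                     baseline_odd_years=5.0)
        assert not res["event"]
        assert res["time_years_from_onset"] == pytest.approx(6.0)

    def test_prevalent_baseline_event(self):
        res = detect_confirmed_edss6([0, 4, 8], [6.0, 6.5, 6.5],
                                     baseline_odd_years=7.0)
        assert res["event"]
        assert res["time_years_from_onset"] == pytest.approx(7.0)

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            detect_confirmed_edss6([0, 6], [6.0, 6.0], baseline_odd_years=np.nan)


class TestEventTable:
    def _cohort(self):
        rows = []
        series = {
            "a": [4.0, 5.0, 5.0, 5.5],      # event at m3
            "b": [4.0, 4.0, 4.0, 4.0],      # censored
            "c": [5.0, 6.0, 5.0, 6.0],      # unconfirmed, censored (strict)
        }
        for sid, vals in series.items():
            for j, v in enumerate(vals):
                rows.append((sid, "T", 6.0 + j * 0.25, "EDSS_raw", v))
        obs = pd.DataFrame(
            rows, columns=["subject_id", "trial", "visit_time_years", "marker", "value"]
        )
        cov = pd.DataFrame({
            "subject_id": list(series), "age_onset": [35.0, 40.0, 45.0],
            "sex": ["M", "F", "M"], "treatment": [1, 0, 1], "trial": ["T"] * 3,
        })
        return LongitudinalCohort(obs, cov)

    def test_event_times_within_followup(self):
        definition = CDPDefinition("CDP-EDSS", "EDSS_raw", "edss")
        ev = build_event_table(self._cohort(), definition)
        assert set(ev["subject_id"]) == {"a", "b", "c"}
        assert ev.set_index("subject_id").loc["a", "event"] == 1
        assert ev.set_index("subject_id").loc["a", "time_months"] == pytest.approx(3.0)
        censored = ev[ev["event"] == 0]
        assert np.allclose(censored["time_months"], 9.0)  # last visit exactly


class TestCox:
    def _null_events(self, rng, n=300):
        group = rng.choice(["G1", "G2", "G3"], size=n, p=[0.15, 0.7, 0.15])
        t = rng.exponential(20.0, size=n)
        cens = rng.uniform(5, 40, size=n)
        return pd.DataFrame({
            "group": group,
            "time_months": np.minimum(t, cens),
            "event": (t <= cens).astype(int),
            "age_onset": rng.normal(39, 9, n),
            "sex": rng.choice(["M", "F"], size=n),
            "treatment": rng.integers(0, 2, size=n),
        })

    def test_null_covariates_leave_contrasts_unchanged(self, rng):
        events = self._null_events(rng)
        res = fit_cox(events)
        uni = res[(res["model"] == "univariable") & (res["contrast"] == "G3 vs G2")]
        multi = res[(res["model"] == "multivariable") & (res["contrast"] == "G3 vs G2")]
        assert abs(np.log(uni["HR"].iloc[0]) - np.log(multi["HR"].iloc[0])) < 0.25

    def test_interaction_rows_reported(self, rng):
        events = self._null_events(rng)
        res = fit_cox(events, interaction=True)
        assert (res["contrast"] == "treatment x G3").any()

    def test_eventless_group_inestimable(self, rng):
        events = self._null_events(rng, n=200)
        events.loc[events["group"] == "G1", "event"] = 0
        res = fit_cox(events, covariates=())
        g1 = res[res["contrast"] == "G1 vs G2"]
        assert g1["HR"].isna().all()
        assert (res["contrast"] == "G3 vs G2").any()


class TestKmLogrank:
    def test_all_events_at_five(self):
        events = pd.DataFrame({
            "group": ["A"] * 10 + ["B"] * 10,
            "time_months": [5.0] * 20,
            "event": [1] * 20,
        })
        res = km_and_logrank(events)
        assert (res["medians"]["median"] == 5.0).all()

    def test_median_not_reached_reported_as_inf(self):
        events = pd.DataFrame({
            "group": ["A"] * 20 + ["B"] * 20,
            "time_months": list(np.linspace(1, 20, 20)) * 2,
            "event": [0] * 20 + [1] * 20,
        })
        res = km_and_logrank(events)
        med = res["medians"].set_index("group")["median"]
        assert np.isinf(med["A"])
        assert np.isfinite(med["B"])

    def test_single_group_rejected(self):
        events = pd.DataFrame({
            "group": ["A"] * 5, "time_months": [1.0] * 5, "event": [1] * 5,
        })
        with pytest.raises(ValueError, match="2 groups"):
            km_and_logrank(events)
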