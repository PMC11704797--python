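"""Core data containers: marker metadata and longitudinal cohorts.

A cohort is stored in long format — one row per (subject, visit, marker)
observation — alongside a per-subject covariate table. Visit time is the
observed disease duration (ODD) in years since reported symptom onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSpec",
    "LongitudinalCohort",
    "DEFAULT_MARKER_SPECS",
    "default_marker_specs",
]

NON_DECREASING = "non-decreasing"
NON_INCREASING = "non-increasing"


@dataclass(frozen=True)
class MarkerSpec:
    """Metadata for one progression marker.

    Parameters
    ----------
    name:
        Marker identifier as used in the long-format table.
    log_transform:
        Whether the raw values are log-transformed before quantile scoring
        (skewed markers: lesion volumes, timed tests).
    monotone_direction:
        Direction of the population trajectory on the raw-oriented modelling
        scale (quantile of the raw value): ``"non-decreasing"`` or
        ``"non-increasing"``. Cognition (SDMT) and brain volume (NBV) decline,
        hence non-increasing; the other six markers worsen upwards.
    worse_is:
        Which end of the *raw* scale is abnormal: ``"higher"`` (EDSS, timed
        tests, lesion volumes) or ``"lower"`` (SDMT, NBV).
    """

    name: str
    log_transform: bool = False
    monotone_direction: str = NON_DECREASING
    worse_is: str = "higher"

    def __post_init__(self) -> None:
        if self.monotone_direction not in (NON_DECREASING, NON_INCREASING):
            raise ValueError(
                f"monotone_direction must be {NON_DECREASING!r} or "
                f"{NON_INCREASING!r}, got {self.monotone_direction!r}"
            )
        if self.worse_is not in ("higher", "lower"):
            raise ValueError(f"worse_is must be 'higher' or 'lower', got {self.worse_is!r}")

    @property
    def direction_sign(self) -> int:
        """+1 for non-decreasing, -1 for non-increasing (modelling scale)."""
        return 1 if self.monotone_direction == NON_DECREASING else -1

    def effective_direction(self, abnormality_oriented: bool) -> str:
        """Trajectory direction on the score scale actually fed to the model.

        When quantile scores are flipped so that 1 = most abnormal
        (``abnormality_oriented=True``), markers whose raw scale declines
        (worse_is='lower') have their direction reversed relative to
        ``monotone_direction``.
        """
        if not abnormality_oriented or self.worse_is == "higher":
            return self.monotone_direction
        return NON_DECREASING if self.monotone_direction == NON_INCREASING else NON_INCREASING


def default_marker_specs() -> list[MarkerSpec]:
    """The eight standard PPMS progression markers.

    Log transforms for the skewed markers (lesion volumes and the timed
    tests); non-increasing constraints for SDMT and NBV, non-decreasing for
    the remaining six.
    """
    return [
        MarkerSpec("EDSS"),
        MarkerSpec("T25FW", log_transform=True),
        MarkerSpec("NHPT_D", log_transform=True),
        MarkerSpec("NHPT_ND", log_transform=True),
        MarkerSpec("SDMT", monotone_direction=NON_INCREASING, worse_is="lower"),
        MarkerSpec("NBV", monotone_direction=NON_INCREASING, worse_is="lower"),
        MarkerSpec("T1LV", log_transform=True),
        MarkerSpec("T2LV", log_transform=True),
    ]


DEFAULT_MARKER_SPECS: list[MarkerSpec] = default_marker_specs()

_OBS_COLUMNS = ["subject_id", "trial", "visit_time_years", "marker", "value"]
_COV_COLUMNS = ["subject_id", "age_onset", "sex", "treatment", "trial"]


@dataclass
class LongitudinalCohort:
    """Long-format longitudinal marker observations plus per-subject covariates.

    ``observations`` columns: subject_id, trial, visit_time_years (ODD),
    marker, value. ``covariates`` columns: subject_id, age_onset, sex,
    treatment, trial (extra columns tolerated and carried along).
    """

    observations: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in _OBS_COLUMNS if c not in self.observations.columns]
        if missing:
            raise ValueError(f"observations missing columns: {missing}")
        obs = self.observations
        if len(obs) and (obs["visit_time_years"].dropna() < 0).any():
            raise ValueError("visit times must be non-negative")
        if self.covariates is None or self.covariates.empty:
            ids = obs["subject_id"].drop_duplicates()
            trial = obs.groupby("subject_id", sort=False)["trial"].first()
            self.covariates = pd.DataFrame(
                {"subject_id": ids.values, "trial": trial.reindex(ids).values}
            )

    # -- accessors -------------------------------------------------------

    @property
    def subject_ids(self) -> list:
        return list(self.covariates["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def markers(self) -> list[str]:
        return sorted(self.observations["marker"].unique())

    def subject_observations(self, subject_id) -> pd.DataFrame:
        return self.observations[self.observations["subject_id"] == subject_id]

    def baseline_times(self) -> pd.Series:
        """Baseline ODD (years) per subject: earliest visit time."""
        return self.observations.groupby("subject_id")["visit_time_years"].min()

    def marker_series(self, subject_id, marker: str) -> pd.DataFrame:
        """Time-sorted (visit_time_years, value) for one subject and marker."""
        sub = self.observations
        sel = sub[(sub["subject_id"] == subject_id) & (sub["marker"] == marker)]
        return sel.sort_values("visit_time_years")[["visit_time_years", "value"]]

    def subset_markers(self, markers: Iterable[str]) -> "LongitudinalCohort":
        keep = set(markers)
        obs = self.observations[self.observations["marker"].isin(keep)].copy()
        return LongitudinalCohort(obs, self.covariates.copy())

    def subset_subjects(self, subject_ids: Sequence) -> "LongitudinalCohort":
        keep = set(subject_ids)
        obs = self.observations[self.observations["subject_id"].isin(keep)].copy()
        cov = self.covariates[self.covariates["subject_id"].isin(keep)].copy()
        return LongitudinalCohort(obs, cov)

    # -- I/O -------------------------------------------------------------

    def to_csv(self, observations_path, covariates_path) -> None:
        self.observations.to_csv(observations_path, index=False)
        self.covariates.to_csv(covariates_path, index=False)

    @classmethod
    def from_csv(cls, observations_path, covariates_path=None) -> "LongitudinalCohort":
        obs = pd.read_csv(observations_path, comment="#")
        cov = pd.read_csv(covariates_path, comment="#") if covariates_path else None
        if cov is None:
            return cls(obs)
        return cls(obs, cov)

    def validate_visits(self) -> None:
        """Check per-subject visit times are strictly increasing per marker."""
        for (sid, marker), grp in self.observations.groupby(["subject_id", "marker"]):
            t = grp["visit_time_years"].to_numpy()
            t = np.sort(t)
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"duplicate visit times for subject {sid!r}, marker {marker!r}"
                )
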