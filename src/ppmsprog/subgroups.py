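"""Progressor subgrouping from the time-reparametrization parameter.

Subjects are partitioned by where their reparametrization parameter
delta = RDD - ODD falls relative to the population distribution: within
k SD of the mean (normative progressors, G2), below -k SD (slow, G1 —
less disability than their disease duration suggests) or above +k SD
(fast, G3 — staged further along than duration suggests). A duration-only
"null" classifier applies the same rule to baseline observed disease
duration, and a baseline-characteristics table compares the groups with
chi-square / ANOVA / Kruskal-Wallis tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LongitudinalCohort

__all__ = [
    "SubgroupAssignment",
    "classify_progressors",
    "null_classify",
    "compare_baseline_characteristics",
    "DegenerateDistributionError",
]

GROUPS = ("G1", "G2", "G3")


class DegenerateDistributionError(ValueError):
    """The classifying parameter has zero variance."""


@dataclass
class SubgroupAssignment:
    """Per-subject progressor labels plus the cutoff that produced them."""

    table: pd.DataFrame          # subject_id, delta_years, label
    k_sd: float
    mean: float
    sd: float
    basis: str = "delta"         # "delta" (model) or "odd" (null classifier)

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("subject_id")["label"]

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(GROUPS, fill_value=0)

    def fractions(self) -> pd.Series:
        c = self.counts()
        return c / c.sum()

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["cutoff_k_sd"] = self.k_sd
        out.to_csv(path, index=False)


def classify_progressors(
    deltas: pd.Series,
    k_sd: float = 1.0,
    flip_sign: bool = False,
) -> SubgroupAssignment:
    """Three-way split of the reparametrization-parameter distribution.

    ``deltas`` holds delta = RDD - ODD per subject (years); with the default
    sign convention the upper tail (staged further along than observed
    duration suggests) is labelled fast (G3) and the lower tail slow (G1).
    ``flip_sign`` reverses the convention.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    d = pd.Series(deltas).astype(float)
    if len(d) < 2:
        raise ValueError("need at least 2 subjects to classify")
    if flip_sign:
        d = -d
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDistributionError("zero variance in the reparametrization parameter")
    z = (d - mean) / sd
    label = pd.Series("G2", index=d.index, dtype=object)
    label[z > k_sd] = "G3"
    label[z < -k_sd] = "G1"
    table = pd.DataFrame(
        {"subject_id": d.index, "delta_years": d.values, "label": label.values}
    )
    return SubgroupAssignment(table=table, k_sd=k_sd, mean=mean, sd=sd, basis="delta")


def null_classify(cohort: LongitudinalCohort, k_sd: float = 1.0) -> SubgroupAssignment:
    """Duration-only comparator: the same ±k·SD rule on baseline ODD.

    Subjects with missing baseline disease duration are excluded with a
    warning. Here the *upper* tail (long duration) plays the role of the
    outlier groups symmetric to the model-based split.
    """
    odd = cohort.baseline_times()
    all_ids = cohort.subject_ids
    missing = [s for s in all_ids if s not in odd.index or not np.isfinite(odd[s])]
    if missing:
        warnings.warn(
            f"{len(missing)} subjects without baseline disease duration excluded"
        )
    odd = odd.dropna()
    assignment = classify_progressors(odd, k_sd=k_sd)
    assignment.basis = "odd"
    assignment.table = assignment.table.rename(columns={"delta_years": "baseline_odd_years"})
    return assignment


def _is_categorical(series: pd.Series) -> bool:
    return (
        series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
        or series.nunique(dropna=True) <= 2
    )


def compare_baseline_characteristics(
    covariates: pd.DataFrame,
    assignment: SubgroupAssignment,
    variables: Sequence[str] | None = None,
    continuous_test: str = "auto",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-group baseline comparison table with hypothesis tests.

    Categorical variables get n (%) per group and a chi-square test;
    continuous variables get mean (SD) with ANOVA or median (IQR) with
    Kruskal-Wallis. ``continuous_test`` is ``"anova"``, ``"kruskal"`` or
    ``"auto"`` (Shapiro normality check per group decides). P-values are
    reported two-sided without multiplicity correction.
    """
    if continuous_test not in ("auto", "anova", "kruskal"):
        raise ValueError("continuous_test must be 'auto', 'anova' or 'kruskal'")
    labels = assignment.labels
    df = covariates.set_index("subject_id").join(labels.rename("label"), how="inner")
    groups_present = [g for g in GROUPS if (df["label"] == g).any()]
    if len(groups_present) < 2:
        raise ValueError("need at least 2 non-empty groups to compare")
    dropped = [g for g in GROUPS if g not in groups_present]
    if dropped:
        warnings.warn(f"empty groups excluded from tests: {dropped}")
    if variables is None:
        variables = [c for c in df.columns if c not in ("label", "trial")]

    rows = []
    for var in variables:
        sub = df[[var, "label"]].dropna()
        by_group = [sub.loc[sub["label"] == g, var] for g in groups_present]
        if _is_categorical(sub[var]):
            ct = pd.crosstab(sub[var], sub["label"])
            ct = ct[[g for g in groups_present if g in ct.columns]]
            if ct.shape[0] < 2 or ct.shape[1] < 2:
                stat, p, test = np.nan, np.nan, "chi2"
            else:
                stat, p, _, _ = stats.chi2_contingency(ct.to_numpy())
                test = "chi2"
            summary = {
                g: " / ".join(
                    f"{lvl}: {int(n)} ({100 * n / max(col.sum(), 1):.1f}%)"
                    for lvl, n in col.items()
                )
                for g, col in ct.items()
            }
        else:
            vals = [g.to_numpy(dtype=float) for g in by_group]
            test = continuous_test
            if test == "auto":
                normal = all(
                    len(v) >= 3 and stats.shapiro(v[:5000]).pvalue > normality_alpha
                    for v in vals
                )
                test = "anova" if normal else "kruskal"
            if any(len(v) < 2 for v in vals):
                stat, p = np.nan, np.nan
            elif test == "anova":
                stat, p = stats.f_oneway(*vals)
            else:
                stat, p = stats.kruskal(*vals)
            if test == "anova":
                summary = {
                    g: f"{np.mean(v):.2f} ({np.std(v, ddof=1):.2f})" if len(v) > 1 else "-"
                    for g, v in zip(groups_present, vals)
                }
            else:
                summary = {
                    g: f"{np.median(v):.2f} ({np.percentile(v, 25):.2f}-{np.percentile(v, 75):.2f})"
                    if len(v) else "-"
                    for g, v in zip(groups_present, vals)
                }
        row = {"variable": var, "test": test, "statistic": float(stat) if np.isfinite(stat) else np.nan,
               "p_value": float(p) if np.isfinite(p) else np.nan}
        for g in GROUPS:
            row[g] = summary.get(g, "")
        rows.append(row)
    return pd.DataFrame(rows)
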