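"""Marker preprocessing: log transforms and empirical quantile scores.

Raw marker values are mapped onto a common [0, 1] modelling scale: skewed
markers (lesion volumes, timed tests) are log-transformed first, then every
marker is converted to its empirical quantile among all pooled observations
of that marker, oriented so that 1 is the most abnormal value (so e.g. the
best cognition score maps to 0, the smallest brain volume to 1).

The quantile convention is (# strictly smaller + half the ties) / n, clamped
to [0, 1] for out-of-sample queries — symmetric tie handling with an exact
0.5 at the median for odd n. No imputation or winsorization is done: the
progression model consumes missingness natively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import LongitudinalCohort, MarkerSpec

__all__ = ["QuantileMap", "fit_quantile_map", "apply_quantile_map"]


class InsufficientDataError(ValueError):
    """A marker has too few observations to fit a reference distribution."""


class UnknownMarkerError(KeyError):
    """Query marker absent from the fitted quantile map."""


@dataclass
class QuantileMap:
    """Per-marker reference distributions for empirical quantile scoring.

    ``reference[marker]`` holds the sorted reference sample on the transform
    scale (log already applied where flagged). ``orient_abnormal`` controls
    whether scores are flipped so 1 = most abnormal (the default contract);
    with ``orient_abnormal=False`` scores follow the raw ordering, matching
    the modelling-scale orientation under which declining markers keep their
    non-increasing direction.
    """

    reference: dict[str, np.ndarray]
    specs: dict[str, MarkerSpec]
    orient_abnormal: bool = True

    def markers(self) -> list[str]:
        return sorted(self.reference)

    def score(self, marker: str, values) -> np.ndarray:
        if marker not in self.reference:
            raise UnknownMarkerError(marker)
        spec = self.specs[marker]
        x = np.asarray(values, dtype=float)
        out = np.full(x.shape, np.nan)
        ok = np.isfinite(x)
        if not ok.any():
            return out
        v = x[ok]
        if spec.log_transform:
            if np.any(v <= 0):
                raise ValueError(f"non-positive value for log-transformed marker {marker!r}")
            v = np.log(v)
        ref = self.reference[marker]
        n = len(ref)
        below = np.searchsorted(ref, v, side="left")
        upto = np.searchsorted(ref, v, side="right")
        q = (below + 0.5 * (upto - below)) / n
        q = np.clip(q, 0.0, 1.0)
        if self.orient_abnormal and spec.worse_is == "lower":
            q = 1.0 - q
        out[ok] = q
        return out

    # -- serialization ---------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "orient_abnormal": self.orient_abnormal,
            "markers": {
                name: {
                    "reference": self.reference[name].tolist(),
                    "log_transform": self.specs[name].log_transform,
                    "monotone_direction": self.specs[name].monotone_direction,
                    "worse_is": self.specs[name].worse_is,
                }
                for name in self.reference
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "QuantileMap":
        with open(path) as fh:
            payload = json.load(fh)
        reference = {}
        specs = {}
        for name, entry in payload["markers"].items():
            reference[name] = np.asarray(entry["reference"], dtype=float)
            specs[name] = MarkerSpec(
                name,
                log_transform=entry["log_transform"],
                monotone_direction=entry["monotone_direction"],
                worse_is=entry["worse_is"],
            )
        return cls(reference, specs, orient_abnormal=payload["orient_abnormal"])


def fit_quantile_map(
    cohort: LongitudinalCohort,
    specs: Sequence[MarkerSpec],
    orient_abnormal: bool = True,
    baseline_only: bool = False,
) -> QuantileMap:
    """Fit per-marker empirical reference distributions from a cohort.

    All visits are pooled by default; ``baseline_only=True`` restricts the
    reference to each subject's first visit as a sensitivity option. Markers
    flagged for log transform are transformed before the reference sample is
    stored.
    """
    obs = cohort.observations
    if baseline_only:
        first = obs.groupby("subject_id")["visit_time_years"].transform("min")
        obs = obs[obs["visit_time_years"] == first]
    reference: dict[str, np.ndarray] = {}
    spec_map: dict[str, MarkerSpec] = {}
    for spec in specs:
        vals = obs.loc[obs["marker"] == spec.name, "value"].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise InsufficientDataError(
                f"marker {spec.name!r} has {len(vals)} observations; need >= 2"
            )
        if spec.log_transform:
            if np.any(vals <= 0):
                raise ValueError(
                    f"non-positive values in log-transformed marker {spec.name!r}"
                )
            vals = np.log(vals)
        reference[spec.name] = np.sort(vals)
        spec_map[spec.name] = spec
    return QuantileMap(reference, spec_map, orient_abnormal=orient_abnormal)


def apply_quantile_map(
    qmap: QuantileMap,
    cohort: LongitudinalCohort,
    passthrough: Sequence[str] = ("EDSS_raw",),
) -> LongitudinalCohort:
    """Replace marker values with quantile scores.

    Missing values stay missing. Scores are in [0, 1] and order-preserving
    with respect to abnormality per marker. Markers absent from the map raise
    ``UnknownMarkerError`` unless listed in ``passthrough`` (the ordinal EDSS
    companion column by default), in which case they are carried unchanged.
    """
    obs = cohort.observations.copy()
    for marker in obs["marker"].unique():
        if marker not in qmap.reference:
            if marker in passthrough:
                continue
            raise UnknownMarkerError(marker)
        sel = obs["marker"] == marker
        obs.loc[sel, "value"] = qmap.score(marker, obs.loc[sel, "value"].to_numpy())
    return LongitudinalCohort(obs, cohort.covariates.copy())
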