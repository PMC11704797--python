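"""Standard seeded synthetic benchmarks for model validation.

Two fixed simulation settings used throughout the test-suite and the
validation script:

* ``standard_benchmark``: 150 subjects, 4 markers with sigmoid trajectories
  (midpoints 5/15/25/20 years, widths matching the generator defaults),
  time-shift SD 3 years — the parameter-recovery workhorse.
* ``ordering_benchmark``: 3 markers with sigmoid midpoints at 5/15/25 years,
  used to check that the peak-rate-of-change ordering recovers the true
  temporal sequence.
"""

from __future__ import annotations

from .cohort import MarkerSpec
from .simulate import SigmoidTrajectory, SimConfig, generate_cohort

__all__ = ["standard_benchmark", "ordering_benchmark"]

STANDARD_SHIFT_SD = 3.0


def standard_benchmark(seed: int = 11, n_subjects: int = 150):
    """Build the 4-marker recovery benchmark cohort.

    Returns (cohort, truth, specs, trajectories)."""
    specs = [MarkerSpec(f"M{i}") for i in range(4)]
    traj = {
        "M0": SigmoidTrajectory(5.0, 6.0),
        "M1": SigmoidTrajectory(15.0, 6.0),
        "M2": SigmoidTrajectory(25.0, 8.0),
        "M3": SigmoidTrajectory(20.0, 10.0),
    }
    config = SimConfig(
        n_subjects=n_subjects,
        marker_specs=specs,
        trajectories=traj,
        shift_sd=STANDARD_SHIFT_SD,
        missing_blocks={},
        emit_edss_raw=False,
        seed=seed,
    )
    cohort, truth = generate_cohort(config)
    return cohort, truth, specs, traj


def ordering_benchmark(seed: int, n_subjects: int = 150):
    """Build the 3-marker temporal-ordering benchmark cohort.

    Sigmoid midpoints at 5, 15 and 25 years define the ground-truth order
    M0 < M1 < M2 of peak rates of change. Returns
    (cohort, truth, specs, trajectories)."""
    specs = [MarkerSpec(f"M{i}") for i in range(3)]
    traj = {
        "M0": SigmoidTrajectory(5.0, 6.0),
        "M1": SigmoidTrajectory(15.0, 6.0),
        "M2": SigmoidTrajectory(25.0, 8.0),
    }
    config = SimConfig(
        n_subjects=n_subjects,
        marker_specs=specs,
        trajectories=traj,
        shift_sd=STANDARD_SHIFT_SD,
        missing_blocks={},
        emit_edss_raw=False,
        seed=seed,
    )
    cohort, truth = generate_cohort(config)
    return cohort, truth, specs, traj
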