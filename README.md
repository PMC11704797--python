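# ppmsprog

Data-driven modelling of disability progression in primary progressive
multiple sclerosis (PPMS). The package reconstructs a multi-decade disease
timeline from short clinical-trial follow-ups by jointly estimating monotone
population trajectories for multimodal disability and MRI markers and a
latent *time-shift* per patient, then uses the individual shifts to identify
slow / normative / fast progressor subgroups and to compare their
confirmed-disability-progression (CDP) outcomes.

## The model

Each subject *s* contributes visits at observed disease duration (ODD)
*t* — years since reported symptom onset — with marker scores
*y*<sub>s</sub>(*t*) on a common [0, 1] quantile scale. Visits are assumed
to occur at an unknown disease time τ with a subject-specific time-shift
*d*<sub>s</sub>:

```
t = τ + d_s,        y_s(t) = f(t − d_s) + η_s + ε
```

where *f* = (*f*₁, …, *f*<sub>K</sub>) are smooth monotone population
trajectories with Gaussian-process priors (one independent GP per marker,
reduced-rank squared-exponential representation), η<sub>s</sub> are
per-subject, per-marker Gaussian random intercepts, and ε is heteroskedastic
Gaussian noise with a per-marker scale. Monotonicity is imposed by virtual
derivative observations through a steep sigmoid link; inference alternates
MAP updates of trajectories, shifts (global 1-D search with Laplace SDs) and
variance parameters. The *reparametrized disease duration* (RDD) of a visit
is *t* − *d*<sub>s</sub>, and the per-subject reparametrization parameter
δ<sub>s</sub> = RDD − ODD = −*d*<sub>s</sub> measures progression severity
relative to the population: subjects beyond ±k·SD of the δ distribution are
slow (G1) / fast (G3) outliers, the rest normative (G2).

Downstream, the package detects CDP events (EDSS step rules, 20% timed-test
worsening, SDMT points-or-percent, confirmed EDSS-6 milestone, each with
scheduled-visit confirmation), fits Cox proportional-hazards contrasts
between subgroups and Kaplan–Meier medians with log-rank tests, and
reproduces the duration-only "null" classification for comparison. A seeded
synthetic-cohort generator with known ground truth (sigmoid trajectories,
Gaussian shifts, trial-blocked missingness, irregular visit schedules) makes
the whole pipeline testable without access-controlled trial data.

## Worked example

```python
import numpy as np
from ppmsprog import (SimConfig, generate_cohort, FitConfig,
                      fit_progression_model, classify_progressors,
                      timeline_span)
from ppmsprog.benchmark import standard_benchmark

cohort, truth, specs, traj = standard_benchmark(seed=11)
model = fit_progression_model(cohort, specs, FitConfig())
r = np.corrcoef(model.shifts, truth.shifts[model.shifts.index])[0, 1]
print(f"shift recovery r = {r:.3f}")
print(f"timeline span    = {timeline_span(model):.1f} years")
assignment = classify_progressors(model.deltas, k_sd=1.0)
print(assignment.counts().to_dict())
```

Output:

```
shift recovery r = 0.933
timeline span    = 89.9 years
{'G1': 21, 'G2': 102, 'G3': 27}
```

The correlation says the model recovered the simulated per-subject
time-shifts (true SD 3 years) from ~10 visits per subject spanning only
~2.4 years each; the span is the reconstructed disease-time axis covered by
the cohort once every visit is mapped to RDD (its right tail is driven by
the log-normal baseline-duration distribution of the synthetic cohort); the
counts are the slow / normative / fast progressor split at the 1-SD cutoff.

The same workflow runs from the shell:

```bash
ppmsprog run-all --n-subjects 200 --seed 42 --out-dir run42
```

writing trajectory/ordering/percent-change/shift-distribution figures, the
subgroup and baseline-characteristics tables, the Cox table and KM curves,
and the serialized model into `run42/`.

## Validation script

`scripts/acceptance.py` re-runs the full validation from scratch: it
generates the standard seeded benchmark, fits the progression model,
reports shift recovery and held-out staging correlations, classifies
subgroups, overlays proportional-hazards event times driven by the true
subgroups, and fits the Cox/KM analyses:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
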