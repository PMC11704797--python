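# Methods

## Model

Observed data are long-format longitudinal marker measurements: subject
*s*, visit time *t* (observed disease duration, ODD, in years since
reported symptom onset), marker *k*, value *y*. After preprocessing all
markers live on a [0, 1] quantile-score scale. The generative model is

y_sk(t) = f_k(t − d_s) + b_sk + ε_k,

with

* **f_k** — population trajectory of marker *k* over disease time τ, a
  Gaussian process with squared-exponential kernel, constrained to be
  monotone in the marker's declared direction;
* **d_s** — subject time-shift (years), prior Normal(0, σ_d²); the visit's
  reparametrized disease duration is RDD = t − d_s, and δ_s = −d_s is the
  reparametrization parameter used for subgrouping;
* **b_sk** — per-subject, per-marker random intercept, Normal(0, σ_b²)
  (the minimal random-effect structure that is identifiable against d_s at
  this scale; a time-varying subject process is a possible extension);
* **ε_k** — Gaussian noise with per-marker scale σ_k ("heteroskedastic"
  is read as across-marker; time-varying noise is not modelled).

### Reduced-rank GP and monotonicity

f_k is represented with the Hilbert-space (sine-eigenbasis) reduced-rank
approximation of the SE kernel on a domain covering every stage reachable
given the data and the shift search bound. Weight priors are the SE
spectral density evaluated at the basis frequencies. Monotonicity is
enforced with virtual-derivative observations: at 200 grid points spanning
the whole domain, the derivative (analytic in the basis) is pushed through
a sigmoid link of scale ν = 2·10⁻⁴ score/year; wrong-signed slopes are
penalised proportionally to their magnitude. The grid is static over the
full reachable domain on purpose — a grid tracking only the current stage
range leaves the constraint unenforced wherever later shift updates move
the data, which manifests as spurious dips at the timeline edges. With the
default settings the fitted posterior means violate their direction by
less than 10⁻³ score units per step on a 200-point grid (typically
< 10⁻⁴).

### Inference

Block-coordinate MAP with Laplace uncertainty:

1. **Trajectory weights** per marker: L-BFGS on the penalised Gaussian
   likelihood (analytic gradients).
2. **Subject shifts**: the per-subject 1-D negative log posterior, with
   the random intercepts *profiled out in closed form*, is minimised by a
   global grid search (61 points over ±15 y) plus bounded refinement.
   Profiling matters: it makes the shift objective a deterministic
   function of the trajectories, so staging new subjects uses literally
   the same computation as training and self-staging is exact.
3. **Scales**: σ_k from residuals (floor 10⁻³), σ_d from the shift sample
   moment (floor 0.5 y).
4. Shift posterior SDs from the numerical curvature of the profiled
   objective at the MAP; trajectory posterior covariance from the Laplace
   Hessian at the weight MAP (data term + prior + monotonicity-penalty
   curvature). Trajectory realizations are Cholesky draws from this
   Gaussian.

Initialization: shifts are warm-started by ranking subjects on mean
oriented abnormality (per-marker z-scores averaged within subject) and
mapping the rank onto the empirical baseline-ODD distribution. Starting
from zero shifts instead leaves the alternation in compressed-timeline
local optima on a minority of seeds; the warm start uses no ground-truth
information.

Convergence: relative objective change ≤ 10⁻⁵ or the iteration cap
(default 25); hitting the cap raises a warning and sets
`converged=False` — the tail of the objective decreases by ≈10⁻⁵/iteration
at that point, so fitted quantities are stable.

Gauge: the model is invariant under d_s → d_s − c, f(τ) → f(τ − c). After
fitting, shifts are centred and the constant absorbed into the stored time
origin, so the mean fitted shift is 0 by construction.

## Preprocessing

Skewed markers (lesion volumes, timed tests) are log-transformed, then each
marker is mapped to its empirical quantile among all pooled observations:
q = (#strictly smaller + ½·#ties)/n, clamped to [0, 1] out of sample —
symmetric ties, exact 0.5 at an odd-n median. Scores are oriented so 1 is
most abnormal; for declining markers (SDMT, NBV) this flip also reverses
the trajectory direction passed to the model
(`MarkerSpec.effective_direction`). The raw-oriented modelling scale (no
flip), under which SDMT/NBV keep non-increasing trajectories, is available
via `orient_abnormal=False`. Held-out cohorts are scored with the training
map (no refit). No imputation: missing entries simply contribute nothing to
the likelihood.

## Synthetic cohorts

The generator emulates the pooled-trial setting the model targets: visits
every 2.76 months (truncated-normal jitter, SD 0.3) over follow-ups of
28.2 ± 10.8 months; baseline disease duration log-normal with median 6.3 y
calibrated to IQR 3.7–9.8 y; time-shifts Normal(0, shift_sd²) centred
(default SD 3 y); monotone sigmoid trajectories on the score scale with
marker-specific midpoints/widths; per-subject intercepts (SD 0.04) and
Gaussian noise (SD 0.05) with clipping to [0, 1]; trial-blocked
missingness (cognition score only in ~24% of subjects, T1 lesion volume
absent from one trial); an ordinal EDSS companion column on the 0–10
half-point scale for event-detection tests. Ground truth (trajectories,
shifts, labels) is returned for recovery checks, and a
proportional-hazards exponential overlay generates subgroup-driven event
times for survival analyses.

What the generator does **not** emulate: relapse dynamics, non-monotone
marker fluctuations, visit-schedule informativeness (dropout independent
of state), cross-marker noise correlation, and any treatment effect. A
green recovery test therefore establishes that the estimation machinery
works under the stated world, not that the model is robust to those
real-data features.

## Subgroups and outcomes

δ_s = RDD − ODD; subjects with δ within ±k·SD of the mean are normative
(G2), upper tail fast (G3: more disability than duration suggests), lower
tail slow (G1); the sign convention is flippable. The SD is the plain
sample SD of the posterior-mean δ (posterior spread not propagated into
the cutoff). A duration-only null classifier applies the same rule to
baseline ODD. Baseline tables use χ² for categoricals and ANOVA or
Kruskal–Wallis (auto-selected by per-group Shapiro tests, or forced) for
continuous variables, two-sided p, no multiplicity correction.

CDP rules: EDSS +1.0 from baseline 3.0–5.0 / +0.5 from 5.5–6.5 (out-of-band
baselines: +1.0 below 3.0, +0.5 at ≥7.0, flagged); ≥20% worsening for timed
tests; SDMT −3 points or −10% with 6-month confirmation; confirmed EDSS-6
milestone reported on the years-since-onset axis (prevalent confirmed
baselines count as events at baseline). "Confirmed at a scheduled visit at
least 3 months later" defaults to the sustained reading — every visit from
the candidate through the first visit ≥ the window must qualify; a lenient
mode checks only the confirmation visit. Fixed study baseline, no
re-baselining. Cox models (Efron ties) and KM/log-rank are delegated to
lifelines; contrasts are G1 vs G2 and G3 vs G2, univariable and
multivariable (age at onset, sex, treatment; optional
treatment-by-subgroup interaction), with eventless contrasts reported as
inestimable.

## Numerical choices and degenerate inputs

* Basis size 25, lengthscale 8 y, signal SD 0.6, boundary factor 1.3 —
  smooth non-wiggly trajectories over a ~50-year axis.
* Shift search bound ±15 y; grid 61 points; Laplace SD fallback 10 y when
  the curvature is non-positive (flat likelihood).
* Flat markers in the peak-rate ordering (max |f′| < 10⁻⁴) are flagged
  undefined and reported last with an interval covering the whole span.
* All-missing markers are dropped with a warning; staging a subject with
  zero usable observations raises an error naming the subject.
* Every random quantity flows from a single integer seed per entry point.

## Known limitations

Per-marker independent GPs (no cross-marker kernel); intercept-only random
effects; MAP + Laplace rather than full posterior (shift SDs are local
curvatures and can understate multimodal uncertainty for subjects with
flat plateau data); the benchmark's ~0.93 shift-recovery correlation is
for the stated synthetic world at n=150 and degrades with fewer markers or
subjects; subgroup fractions on fitted deltas are heavier-tailed than the
Gaussian oracle because estimation error inflates the tails.
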