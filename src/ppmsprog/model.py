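"""Monotone Gaussian-process progression model with latent time-shifts.

The model treats each subject's visits as samples from a shared set of
population trajectories evaluated at an unknown *disease time* tau, with the
mapping from observed disease duration (ODD) t to disease time given by a
subject-specific shift: t = tau + d_s. Observations for marker k of subject
s are

    y_sk(t) = f_k(t - d_s) + b_sk + eps_k,

where f_k is a smooth monotone population trajectory with a Gaussian-process
prior, b_sk a per-subject, per-marker Gaussian random intercept, and eps_k
Gaussian heteroskedastic noise (per-marker scale sigma_k). Each subject's
reparametrized disease duration (RDD) at a visit is t - d_s; the collection
of shifts places every subject on a common long-term timeline reconstructed
from short follow-ups.

Implementation notes
--------------------
* f_k is represented with a reduced-rank (Hilbert-space) approximation of a
  squared-exponential GP: a sine eigenbasis on the disease-time domain with
  prior weight variances given by the SE spectral density. This keeps every
  update a small dense linear-algebra problem, gives analytic derivatives
  (for peak-rate-of-change ordering), and makes posterior sampling of whole
  trajectories a Cholesky draw.
* Monotonicity is a population-level soft constraint: virtual derivative
  observations at grid points pushed through a steep sigmoid link penalise
  any slope of the wrong sign. Subject-level curves are not constrained.
* Inference alternates MAP updates of trajectory weights (L-BFGS), random
  intercepts (closed form), subject shifts (global grid search + local
  polish, Laplace SDs), and noise/shift-prior scales, until the joint
  negative log posterior stabilises. Shifts are centred at the end and the
  centring constant absorbed into the trajectory's time origin, fixing the
  translation gauge.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, log_expit

from .cohort import LongitudinalCohort, MarkerSpec

__all__ = [
    "FitConfig",
    "FittedProgressionModel",
    "fit_progression_model",
    "stage_new_subjects",
    "sample_trajectories",
    "peak_rate_ordering",
    "percent_change",
    "timeline_span",
    "StagingError",
]


class StagingError(ValueError):
    """A subject cannot be staged (no usable observations)."""


@dataclass
class FitConfig:
    """Tunable parameters of the progression-model fit.

    The kernel hyperparameters are fixed: ``lengthscale`` (years) keeps the
    trajectories non-wiggly over a multi-decade axis and ``signal_sd`` sets
    the prior amplitude on the [0, 1] score scale. Noise scales and the
    shift-prior SD are re-estimated during fitting.
    """

    n_basis: int = 25
    lengthscale: float = 8.0            # years; smoothness of f_k
    signal_sd: float = 0.6              # prior SD of f_k around its 0.5 mean
    boundary_factor: float = 1.3        # Hilbert-basis domain extension
    shift_bound: float = 15.0           # years; search bound for |d_s|
    shift_prior_sd: float = 5.0         # initial SD of the shift prior
    update_shift_prior: bool = True
    intercept_prior_sd: float = 0.05    # score units
    noise_init: float = 0.1
    noise_floor: float = 1e-3
    update_noise: bool = True
    mono_grid_size: int = 200
    mono_nu: float = 2e-4               # slope scale of the monotonicity link
    mono_weight: float = 1.0
    max_outer: int = 25
    rel_tol: float = 1e-5
    shift_grid_size: int = 61
    domain_pad: float = 2.0             # years beyond the reachable stage range
    init_shifts: str = "severity"       # "severity" rank-based warm start, or "zero"
    seed: int = 0


class _HilbertBasis:
    """Reduced-rank SE-GP basis: sine eigenfunctions on [-L, L] + centre."""

    def __init__(self, lo: float, hi: float, n_basis: int, lengthscale: float,
                 signal_sd: float, boundary_factor: float = 1.3):
        self.lo = float(lo)
        self.hi = float(hi)
        self.centre = 0.5 * (lo + hi)
        self.L = 0.5 * (hi - lo) * boundary_factor
        j = np.arange(1, n_basis + 1)
        self.freq = np.pi * j / (2.0 * self.L)
        self.prior_var = (
            signal_sd ** 2 * np.sqrt(2.0 * np.pi) * lengthscale
            * np.exp(-0.5 * (lengthscale * self.freq) ** 2)
        )
        # guard against numerically zero prior variances for high frequencies
        self.prior_var = np.maximum(self.prior_var, 1e-12)
        self.n_basis = n_basis
        self.lengthscale = lengthscale
        self.signal_sd = signal_sd
        self.boundary_factor = boundary_factor

    def design(self, tau) -> np.ndarray:
        x = np.atleast_1d(np.asarray(tau, dtype=float)) - self.centre + self.L
        return np.sin(np.outer(x, self.freq)) / np.sqrt(self.L)

    def ddesign(self, tau) -> np.ndarray:
        x = np.atleast_1d(np.asarray(tau, dtype=float)) - self.centre + self.L
        return np.cos(np.outer(x, self.freq)) * self.freq / np.sqrt(self.L)


def _prepare_marker_data(cohort: LongitudinalCohort, markers: Sequence[str]):
    """Per-marker observation arrays with integer subject indices."""
    sid_index = {sid: i for i, sid in enumerate(cohort.subject_ids)}
    obs = cohort.observations.dropna(subset=["value"])
    data = {}
    for m in markers:
        sel = obs[obs["marker"] == m]
        if sel.empty:
            continue
        data[m] = {
            "t": sel["visit_time_years"].to_numpy(dtype=float),
            "y": sel["value"].to_numpy(dtype=float),
            "sidx": sel["subject_id"].map(sid_index).to_numpy(dtype=int),
        }
    return data


def _fit_weights(basis, data_k, shifts, intercepts_k, sigma_k, sign, mono_grid,
                 nu, mono_weight, w0, max_newton: int = 60, grad_tol: float = 1e-6):
    """MAP update of one marker's trajectory weights.

    The objective (Gaussian likelihood + Gaussian prior + convex
    virtual-derivative penalty) is convex in the weights, so a damped Newton
    iteration with the exact Hessian converges reliably even though the
    penalty is numerically stiff (quasi-Newton methods stall on it)."""
    tau = data_k["t"] - shifts[data_k["sidx"]]
    phi = basis.design(tau)
    resid_target = data_k["y"] - 0.5 - intercepts_k[data_k["sidx"]]
    dphi_g = basis.ddesign(mono_grid)
    inv_prior = 1.0 / basis.prior_var
    inv_s2 = 1.0 / sigma_k ** 2
    data_hess = inv_s2 * (phi.T @ phi) + np.diag(inv_prior)
    eye = 1e-10 * np.eye(len(w0))

    def value(w):
        r = resid_target - phi @ w
        a = sign * (dphi_g @ w) / nu
        return (0.5 * inv_s2 * r @ r + 0.5 * np.sum(inv_prior * w * w)
                - mono_weight * np.sum(log_expit(a)))

    w = w0.copy()
    f_cur = value(w)
    for _ in range(max_newton):
        r = resid_target - phi @ w
        a = sign * (dphi_g @ w) / nu
        s = expit(a)
        grad = (-inv_s2 * (phi.T @ r) + inv_prior * w
                - mono_weight * (dphi_g.T @ ((1.0 - s) * sign / nu)))
        if np.max(np.abs(grad)) < grad_tol:
            break
        hess = data_hess + (dphi_g * (mono_weight * s * (1.0 - s) / nu ** 2)[:, None]).T @ dphi_g
        step = np.linalg.solve(hess + eye, grad)
        # backtracking line search on the convex objective
        alpha = 1.0
        for _ in range(30):
            f_new = value(w - alpha * step)
            if f_new <= f_cur - 1e-4 * alpha * (grad @ step):
                break
            alpha *= 0.5
        else:
            break
        w = w - alpha * step
        f_cur = f_new
    return w


def _weight_covariance(basis, data_k, shifts, sigma_k, sign, mono_grid, nu,
                       mono_weight, w):
    """Laplace covariance of one marker's weights at the MAP."""
    tau = data_k["t"] - shifts[data_k["sidx"]]
    phi = basis.design(tau)
    dphi_g = basis.ddesign(mono_grid)
    a = sign * (dphi_g @ w) / nu
    s = expit(a)
    H = phi.T @ phi / sigma_k ** 2 + np.diag(1.0 / basis.prior_var)
    H += (dphi_g * (mono_weight * s * (1.0 - s) / nu ** 2)[:, None]).T @ dphi_g
    # symmetrize + jitter for a stable Cholesky
    H = 0.5 * (H + H.T) + 1e-9 * np.eye(len(w))
    return np.linalg.inv(H)


@dataclass
class FittedProgressionModel:
    """Posterior state of the progression model.

    ``subjects`` holds per-subject shift posterior mean/SD, the
    reparametrization parameter delta = RDD - ODD = -shift, and visit counts.
    Trajectories are evaluated through ``trajectory_mean`` /
    ``sample_trajectories``; the time origin offset fixes the centred-shift
    gauge.
    """

    basis: _HilbertBasis
    weights: dict[str, np.ndarray]
    weight_cov: dict[str, np.ndarray]
    directions: dict[str, int]
    noise_sd: dict[str, float]
    intercept_prior_sd: float
    shift_prior_sd: float
    subjects: pd.DataFrame
    intercepts: pd.DataFrame
    tau_offset: float
    tau_range: tuple[float, float]
    objective_trace: list[float]
    converged: bool
    specs: list[MarkerSpec] = field(default_factory=list)
    config: FitConfig = field(default_factory=FitConfig)

    # -- trajectory evaluation ------------------------------------------

    @property
    def markers(self) -> list[str]:
        return list(self.weights)

    def default_grid(self, n: int = 200) -> np.ndarray:
        return np.linspace(self.tau_range[0], self.tau_range[1], n)

    def _phi(self, marker: str, grid, deriv: bool = False) -> np.ndarray:
        g = np.asarray(grid, dtype=float) - self.tau_offset
        return self.basis.ddesign(g) if deriv else self.basis.design(g)

    def trajectory_mean(self, marker: str, grid) -> np.ndarray:
        return 0.5 + self._phi(marker, grid) @ self.weights[marker]

    def trajectory_derivative(self, marker: str, grid) -> np.ndarray:
        return self._phi(marker, grid, deriv=True) @ self.weights[marker]

    def trajectory_band(self, marker: str, grid, z: float = 1.96):
        phi = self._phi(marker, grid)
        mean = 0.5 + phi @ self.weights[marker]
        var = np.einsum("ij,jk,ik->i", phi, self.weight_cov[marker], phi)
        sd = np.sqrt(np.maximum(var, 0.0))
        return mean, mean - z * sd, mean + z * sd

    def monotonicity_violation(self, grid_size: int = 200) -> dict[str, float]:
        """Worst per-step violation of each marker's declared direction."""
        grid = self.default_grid(grid_size)
        out = {}
        for m in self.markers:
            f = self.trajectory_mean(m, grid)
            steps = np.diff(f) * self.directions[m]
            out[m] = float(max(0.0, -steps.min()) if len(steps) else 0.0)
        return out

    @property
    def shifts(self) -> pd.Series:
        return self.subjects.set_index("subject_id")["shift"]

    @property
    def deltas(self) -> pd.Series:
        """Reparametrization parameter delta = RDD - ODD per subject."""
        return -self.shifts

    # -- serialization ---------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "basis": {
                "lo": self.basis.lo, "hi": self.basis.hi,
                "n_basis": self.basis.n_basis,
                "lengthscale": self.basis.lengthscale,
                "signal_sd": self.basis.signal_sd,
                "boundary_factor": self.basis.boundary_factor,
            },
            "weights": {k: v.tolist() for k, v in self.weights.items()},
            "weight_cov": {k: v.tolist() for k, v in self.weight_cov.items()},
            "directions": self.directions,
            "noise_sd": self.noise_sd,
            "intercept_prior_sd": self.intercept_prior_sd,
            "shift_prior_sd": self.shift_prior_sd,
            "subjects": self.subjects.to_dict(orient="list"),
            "intercepts": {
                "index": [str(i) for i in self.intercepts.index],
                "columns": list(self.intercepts.columns),
                "values": self.intercepts.to_numpy().tolist(),
            },
            "tau_offset": self.tau_offset,
            "tau_range": list(self.tau_range),
            "objective_trace": self.objective_trace,
            "converged": self.converged,
            "specs": [
                {"name": s.name, "log_transform": s.log_transform,
                 "monotone_direction": s.monotone_direction, "worse_is": s.worse_is}
                for s in self.specs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FittedProgressionModel":
        with open(path) as fh:
            p = json.load(fh)
        b = p["basis"]
        basis = _HilbertBasis(b["lo"], b["hi"], b["n_basis"], b["lengthscale"],
                              b["signal_sd"], b["boundary_factor"])
        intercepts = pd.DataFrame(
            np.asarray(p["intercepts"]["values"], dtype=float),
            index=p["intercepts"]["index"], columns=p["intercepts"]["columns"],
        )
        return cls(
            basis=basis,
            weights={k: np.asarray(v) for k, v in p["weights"].items()},
            weight_cov={k: np.asarray(v) for k, v in p["weight_cov"].items()},
            directions={k: int(v) for k, v in p["directions"].items()},
            noise_sd={k: float(v) for k, v in p["noise_sd"].items()},
            intercept_prior_sd=p["intercept_prior_sd"],
            shift_prior_sd=p["shift_prior_sd"],
            subjects=pd.DataFrame(p["subjects"]),
            intercepts=intercepts,
            tau_offset=p["tau_offset"],
            tau_range=tuple(p["tau_range"]),
            objective_trace=list(p["objective_trace"]),
            converged=bool(p["converged"]),
            specs=[MarkerSpec(**s) for s in p["specs"]],
        )


def _subject_shift_objective(subject_data, basis, weights, noise_sd,
                             intercept_prior_sd, shift_prior_sd, tau_offset=0.0):
    """Profiled negative log posterior of one subject's shift.

    The per-marker random intercept is profiled out in closed form at every
    candidate shift, so the same deterministic 1-D objective drives both the
    training updates and the staging of new subjects (self-staging lands on
    the fit's own optimum)."""

    def g(d):
        total = 0.5 * d * d / shift_prior_sd ** 2
        for m, t, y in subject_data:
            f = 0.5 + basis.design(t - d - tau_offset) @ weights[m]
            r = y - f
            s2 = noise_sd[m] ** 2
            a = len(r) / s2 + 1.0 / intercept_prior_sd ** 2
            b = np.sum(r) / s2
            total += 0.5 * (r @ r) / s2 - 0.5 * b * b / a
        return total

    return g


def _profiled_intercepts(subject_data, basis, weights, noise_sd,
                         intercept_prior_sd, d, tau_offset=0.0):
    out = {}
    for m, t, y in subject_data:
        f = 0.5 + basis.design(t - d - tau_offset) @ weights[m]
        r = y - f
        s2 = noise_sd[m] ** 2
        out[m] = float(np.sum(r) / s2 / (len(r) / s2 + 1.0 / intercept_prior_sd ** 2))
    return out


def _optimize_shift(g, bound, grid_size):
    grid = np.linspace(-bound, bound, grid_size)
    vals = np.array([g(d) for d in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    res = minimize_scalar(g, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def _shift_laplace_sd(g, d_hat, h=0.05, fallback=10.0):
    curv = (g(d_hat + h) - 2.0 * g(d_hat) + g(d_hat - h)) / h ** 2
    if curv <= 0:
        return fallback
    return float(1.0 / np.sqrt(curv))


def _severity_init_shifts(cohort, data, markers, directions, bound) -> np.ndarray:
    """Warm-start shifts by ranking subjects on mean oriented abnormality.

    Each subject's observations are z-scored per marker, oriented so larger
    means later-stage, and averaged; the severity rank is mapped onto the
    empirical baseline-duration distribution to give an initial stage, whose
    difference from the observed baseline duration seeds the shift. This
    keeps the alternating optimization out of compressed-timeline local
    optima; the warm start carries no ground-truth information.
    """
    n_subj = cohort.n_subjects
    score_sum = np.zeros(n_subj)
    score_cnt = np.zeros(n_subj)
    for m in markers:
        dk = data[m]
        mu, sd = dk["y"].mean(), dk["y"].std()
        if sd == 0:
            continue
        z = directions[m] * (dk["y"] - mu) / sd
        score_sum += np.bincount(dk["sidx"], weights=z, minlength=n_subj)
        score_cnt += np.bincount(dk["sidx"], minlength=n_subj)
    sev = np.divide(score_sum, score_cnt, out=np.zeros(n_subj), where=score_cnt > 0)
    base = cohort.baseline_times().reindex(cohort.subject_ids).to_numpy(dtype=float)
    order = np.argsort(np.argsort(sev))
    p = (order + 0.5) / n_subj
    stage0 = np.quantile(base[np.isfinite(base)], p)
    shifts = np.where(np.isfinite(base), base - stage0, 0.0)
    shifts = np.clip(shifts, -bound, bound)
    return shifts - shifts.mean()


def fit_progression_model(
    cohort: LongitudinalCohort,
    specs: Sequence[MarkerSpec],
    config: FitConfig | None = None,
    abnormality_oriented: bool = False,
) -> FittedProgressionModel:
    """Fit the monotone GP progression model by alternating MAP updates.

    Parameters
    ----------
    cohort:
        Preprocessed cohort with marker values on the [0, 1] score scale.
    specs:
        Marker metadata; only markers present in the cohort are fitted,
        markers with no observations at all are dropped with a warning.
    config:
        Fit configuration (see :class:`FitConfig`).
    abnormality_oriented:
        Set when scores were flipped so 1 = most abnormal; trajectory
        directions are then mapped through
        :meth:`MarkerSpec.effective_direction`.
    """
    config = config or FitConfig()
    if cohort.n_subjects < 2:
        raise ValueError("need at least 2 subjects to fit")
    spec_list = [s for s in specs]
    names = [s.name for s in spec_list]
    data = _prepare_marker_data(cohort, names)
    dropped = [n for n in names if n not in data]
    if dropped:
        warnings.warn(f"markers with no observations dropped: {dropped}")
    spec_list = [s for s in spec_list if s.name in data]
    if not spec_list:
        raise ValueError("no markers with observations")
    n_obs_per_subj = np.bincount(
        np.concatenate([data[s.name]["sidx"] for s in spec_list]),
        minlength=cohort.n_subjects,
    )
    if not (n_obs_per_subj >= 2).any():
        raise ValueError("need at least one subject with >= 2 observations")

    directions = {
        s.name: (1 if s.effective_direction(abnormality_oriented) == "non-decreasing" else -1)
        for s in spec_list
    }
    markers = [s.name for s in spec_list]
    subject_ids = cohort.subject_ids
    n_subj = len(subject_ids)

    t_all = cohort.observations["visit_time_years"].to_numpy(dtype=float)
    lo = float(t_all.min()) - config.shift_bound - config.domain_pad
    hi = float(t_all.max()) + config.shift_bound + config.domain_pad
    basis = _HilbertBasis(lo, hi, config.n_basis, config.lengthscale,
                          config.signal_sd, config.boundary_factor)

    # per-subject observation lists for the shift updates
    per_subject: list[list[tuple[str, np.ndarray, np.ndarray]]] = [[] for _ in range(n_subj)]
    for m in markers:
        dk = data[m]
        for i in range(n_subj):
            sel = dk["sidx"] == i
            if sel.any():
                per_subject[i].append((m, dk["t"][sel], dk["y"][sel]))

    if config.init_shifts == "severity":
        shifts = _severity_init_shifts(cohort, data, markers, directions,
                                       config.shift_bound)
    else:
        shifts = np.zeros(n_subj)
    shift_sds = np.full(n_subj, config.shift_prior_sd)
    intercepts = {m: np.zeros(n_subj) for m in markers}
    sigma = {m: config.noise_init for m in markers}
    sigma_d = config.shift_prior_sd
    weights = {m: np.zeros(config.n_basis) for m in markers}

    # static monotonicity grid over the whole reachable stage domain, so the
    # constraint still holds wherever later shift updates move the data
    mono_grid = np.linspace(lo, hi, config.mono_grid_size)

    trace: list[float] = []
    converged = False
    for outer in range(config.max_outer):
        # (1) trajectory weights
        for m in markers:
            weights[m] = _fit_weights(
                basis, data[m], shifts, intercepts[m], sigma[m], directions[m],
                mono_grid, config.mono_nu, config.mono_weight, weights[m],
            )
        # (2) random intercepts (closed form)
        for m in markers:
            dk = data[m]
            r = dk["y"] - 0.5 - basis.design(dk["t"] - shifts[dk["sidx"]]) @ weights[m]
            num = np.bincount(dk["sidx"], weights=r, minlength=n_subj) / sigma[m] ** 2
            den = (np.bincount(dk["sidx"], minlength=n_subj) / sigma[m] ** 2
                   + 1.0 / config.intercept_prior_sd ** 2)
            intercepts[m] = num / den
        # (3) subject shifts (intercepts profiled out)
        for i in range(n_subj):
            if not per_subject[i]:
                continue
            g = _subject_shift_objective(per_subject[i], basis, weights, sigma,
                                         config.intercept_prior_sd, sigma_d)
            shifts[i] = _optimize_shift(g, config.shift_bound, config.shift_grid_size)
        # (4) noise and shift-prior scales
        total_nll = 0.0
        for m in markers:
            dk = data[m]
            r = (dk["y"] - 0.5 - basis.design(dk["t"] - shifts[dk["sidx"]]) @ weights[m]
                 - intercepts[m][dk["sidx"]])
            if config.update_noise:
                sigma[m] = float(max(np.sqrt(np.mean(r * r)), config.noise_floor))
            total_nll += 0.5 * np.sum(r * r) / sigma[m] ** 2 + len(r) * np.log(sigma[m])
        if config.update_shift_prior:
            sigma_d = float(max(np.sqrt(np.mean(shifts ** 2)), 0.5))
        total_nll += 0.5 * np.sum(shifts ** 2) / sigma_d ** 2
        trace.append(total_nll)
        if outer >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= config.rel_tol * (abs(prev) + 1.0):
                converged = True
                break
    if not converged:
        warnings.warn(
            f"progression-model fit did not converge in {config.max_outer} iterations"
        )

    # Laplace SDs of the shifts at the MAP; final intercepts at the MAP shift
    for i in range(n_subj):
        if not per_subject[i]:
            continue
        g = _subject_shift_objective(per_subject[i], basis, weights, sigma,
                                     config.intercept_prior_sd, sigma_d)
        shift_sds[i] = _shift_laplace_sd(g, shifts[i])
        ints = _profiled_intercepts(per_subject[i], basis, weights, sigma,
                                    config.intercept_prior_sd, shifts[i])
        for m, b in ints.items():
            intercepts[m][i] = b

    # gauge fixing: centre the shifts, absorb the constant into the time origin
    # d_new = d_old - centre requires f_new(tau) = f_old(tau - centre), i.e.
    # evaluating the basis at tau - tau_offset with tau_offset = +centre.
    centre = float(shifts.mean())
    shifts = shifts - centre
    tau_offset = centre

    rdd_min = min(float((data[m]["t"] - shifts[data[m]["sidx"]]).min()) for m in markers)
    rdd_max = max(float((data[m]["t"] - shifts[data[m]["sidx"]]).max()) for m in markers)

    weight_cov = {
        m: _weight_covariance(basis, data[m], shifts + centre, sigma[m],
                              directions[m], mono_grid,
                              config.mono_nu, config.mono_weight, weights[m])
        for m in markers
    }

    base_t = cohort.baseline_times()
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "shift": shifts,
            "shift_sd": shift_sds,
            "delta": -shifts,
            "n_obs": n_obs_per_subj,
            "baseline_odd": [float(base_t.get(s, np.nan)) for s in subject_ids],
        }
    )
    intercept_df = pd.DataFrame(
        {m: intercepts[m] for m in markers}, index=subject_ids
    )
    return FittedProgressionModel(
        basis=basis,
        weights=weights,
        weight_cov=weight_cov,
        directions=directions,
        noise_sd=sigma,
        intercept_prior_sd=config.intercept_prior_sd,
        shift_prior_sd=sigma_d,
        subjects=subjects,
        intercepts=intercept_df,
        tau_offset=tau_offset,
        tau_range=(rdd_min, rdd_max),
        objective_trace=trace,
        converged=converged,
        specs=spec_list,
        config=config,
    )


def stage_new_subjects(
    model: FittedProgressionModel,
    cohort: LongitudinalCohort,
) -> pd.DataFrame:
    """Probabilistic temporal staging of unseen subjects.

    Population trajectories and noise scales stay fixed; only each subject's
    time-shift (with random intercepts profiled out) posterior is inferred —
    the same 1-D objective that drives the training updates, so staging the
    training subjects reproduces their fitted shifts. Returns a table with
    the shift expectation and Laplace SD, the reparametrization parameter
    delta = -shift, and per-subject RDD at baseline. Markers absent from the
    cohort (e.g. a trial that never measured upper-limb function) are simply
    skipped.
    """
    known = set(model.markers)
    sid_list = cohort.subject_ids
    rows = []
    base_t = cohort.baseline_times()
    obs = cohort.observations.dropna(subset=["value"])
    for sid in sid_list:
        sub = obs[obs["subject_id"] == sid]
        subject_data = []
        for m, grp in sub.groupby("marker"):
            if m not in known:
                continue
            subject_data.append(
                (m, grp["visit_time_years"].to_numpy(dtype=float),
                 grp["value"].to_numpy(dtype=float))
            )
        if not subject_data or sum(len(t) for _, t, _ in subject_data) == 0:
            raise StagingError(f"subject {sid!r} has no usable observations")
        g = _subject_shift_objective(
            subject_data, model.basis, model.weights, model.noise_sd,
            model.intercept_prior_sd, model.shift_prior_sd,
            tau_offset=model.tau_offset,
        )
        d = _optimize_shift(g, model.config.shift_bound,
                            model.config.shift_grid_size)
        sd = _shift_laplace_sd(g, d)
        b0 = float(base_t.get(sid, np.nan))
        rows.append(
            {
                "subject_id": sid,
                "shift": d,
                "shift_sd": sd,
                "delta": -d,
                "baseline_odd": b0,
                "baseline_rdd": b0 - d,
            }
        )
    return pd.DataFrame(rows)


def sample_trajectories(
    model: FittedProgressionModel,
    n_samples: int,
    grid=None,
    seed: int | None = 0,
) -> dict[str, np.ndarray]:
    """Posterior draws of every population trajectory on a stage grid.

    Returns ``{marker: (n_samples, len(grid)) array}``; the mean of draws
    converges to the posterior-mean trajectory as n_samples grows.
    """
    if grid is None:
        grid = model.default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    rng = np.random.default_rng(seed)
    out = {}
    for m in model.markers:
        phi = model._phi(m, grid)
        cov = model.weight_cov[m]
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        z = rng.standard_normal((n_samples, len(cov)))
        w_draws = model.weights[m][None, :] + z @ chol.T
        out[m] = 0.5 + w_draws @ phi.T
    return out


def peak_rate_ordering(
    model: FittedProgressionModel,
    n_samples: int = 200,
    grid_size: int = 400,
    seed: int | None = 0,
    flat_tol: float = 0.01,
) -> pd.DataFrame:
    """Temporal ordering of markers by peak rate of change.

    For each posterior draw the stage tau maximising |f_k'| is located on a
    fine grid; markers are ordered by the median peak stage, with a 95%
    credible interval over draws. Markers with no detectable global change
    (posterior-mean |f(tau_max) - f(tau_min)| < flat_tol score units) have
    no meaningful peak: they are flagged undefined and reported last with an
    interval covering the whole timeline.
    """
    grid = model.default_grid(grid_size)
    rng = np.random.default_rng(seed)
    rows = []
    for m in model.markers:
        dphi = model._phi(m, grid, deriv=True)
        f = model.trajectory_mean(m, grid)
        if abs(f[-1] - f[0]) < flat_tol:
            warnings.warn(f"marker {m!r} has no detectable rate of change; peak undefined")
            rows.append({"marker": m, "tau_peak_median": np.nan,
                         "tau_peak_lo": model.tau_range[0],
                         "tau_peak_hi": model.tau_range[1],
                         "undefined": True})
            continue
        cov = model.weight_cov[m]
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        z = rng.standard_normal((n_samples, len(cov)))
        w_draws = model.weights[m][None, :] + z @ chol.T
        slopes = np.abs(w_draws @ dphi.T)           # (n_samples, G)
        peaks = grid[np.argmax(slopes, axis=1)]
        rows.append({
            "marker": m,
            "tau_peak_median": float(np.median(peaks)),
            "tau_peak_lo": float(np.quantile(peaks, 0.025)),
            "tau_peak_hi": float(np.quantile(peaks, 0.975)),
            "undefined": False,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["undefined", "tau_peak_median"], ascending=[True, True],
        na_position="last",
    ).reset_index(drop=True)
    return df


def percent_change(
    model: FittedProgressionModel,
    n_samples: int = 200,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Global percent change of each marker along the estimated timeline.

    100 * |f_k(tau_max) - f_k(tau_min)| / score range (1.0), summarised as
    posterior mean and median over trajectory draws.
    """
    lo, hi = model.tau_range
    draws = sample_trajectories(model, n_samples, grid=np.array([lo, hi]), seed=seed)
    rows = []
    for m in model.markers:
        change = 100.0 * np.abs(draws[m][:, 1] - draws[m][:, 0])
        point = 100.0 * abs(
            float(model.trajectory_mean(m, [hi])[0])
            - float(model.trajectory_mean(m, [lo])[0])
        )
        rows.append({
            "marker": m,
            "percent_change": point,
            "percent_change_mean": float(np.mean(change)),
            "percent_change_median": float(np.median(change)),
        })
    return pd.DataFrame(rows)


def timeline_span(model: FittedProgressionModel) -> float:
    """Span of the reconstructed disease-time axis: max RDD - min RDD (years)."""
    return float(model.tau_range[1] - model.tau_range[0])
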