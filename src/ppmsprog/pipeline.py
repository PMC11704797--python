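"""End-to-end orchestration: simulate/load -> preprocess -> fit -> subgroups
-> outcomes -> figures and tables, under a single seeded configuration.

Every artefact is reproducible from the same config and seed; output tables
carry a config hash and the versions of the libraries of record in a
commented metadata header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import lifelines
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import scipy

from .cohort import LongitudinalCohort, default_marker_specs
from .model import (
    FitConfig,
    FittedProgressionModel,
    fit_progression_model,
    peak_rate_ordering,
    percent_change,
    sample_trajectories,
    stage_new_subjects,
    timeline_span,
)
from .outcomes import CDPDefinition, build_event_table, fit_cox, km_and_logrank
from .preprocess import apply_quantile_map, fit_quantile_map
from .simulate import SimConfig, generate_cohort
from .subgroups import classify_progressors, compare_baseline_characteristics, null_classify

__all__ = ["RunConfig", "RunReport", "run_pipeline", "stage_external", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one input source: either a synthetic :class:`SimConfig` or paths
    to long-format observation / covariate CSVs.
    """

    sim: SimConfig | None = None
    cohort_csv: str | None = None
    covariates_csv: str | None = None
    use_quantile_scores: bool = False   # synthetic scores are already on the modelling scale
    k_sd: list[float] = field(default_factory=lambda: [1.0, 1.5, 2.0])
    endpoints: list[str] = field(default_factory=lambda: ["EDSS"])
    fit: FitConfig = field(default_factory=FitConfig)
    n_realizations: int = 100
    out_dir: str = "ppmsprog_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.cohort_csv is None):
            raise ValueError("exactly one input source: sim config or cohort CSV")
        if any(k <= 0 for k in self.k_sd):
            raise ValueError("k_sd values must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        fit = raw.pop("fit", None)
        cfg = cls(
            sim=SimConfig(**sim) if sim is not None else None,
            fit=FitConfig(**fit) if fit is not None else FitConfig(),
            **raw,
        )
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # output location is not part of the science
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Paths to all produced artefacts plus summary metrics."""

    out_dir: str
    tables: dict[str, str]
    figures: dict[str, str]
    model_path: str
    metrics: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _metadata_header(config: RunConfig) -> str:
    return (
        f"# config_hash: {config.config_hash()}\n"
        f"# seed: {config.seed}\n"
        f"# numpy: {np.__version__} scipy: {scipy.__version__} "
        f"pandas: {pd.__version__} lifelines: {lifelines.__version__}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_header(config))
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis and write tables, figures and the model archive.

    Stages: input -> preprocessing -> progression-model fit -> subgroup
    classification (every configured k-SD cutoff, plus the duration-only
    null classifier) -> baseline tables -> CDP outcomes with Cox and
    Kaplan-Meier analyses -> figures. Any stage failure raises
    :class:`PipelineError` naming the stage; artefacts written so far remain
    on disk as a partial-output manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, str] = {}
    figures: dict[str, str] = {}
    metrics: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    manifest = out / "manifest.json"

    def _save_manifest():
        with open(manifest, "w") as fh:
            json.dump({"tables": tables, "figures": figures, "metrics": metrics},
                      fh, indent=1, default=str)

    # ---- stage: input --------------------------------------------------
    try:
        truth = None
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            cohort, truth = generate_cohort(sim)
        else:
            cohort = LongitudinalCohort.from_csv(config.cohort_csv, config.covariates_csv)
        specs = [s for s in default_marker_specs() if s.name in set(cohort.markers)]
        if not specs:
            from .cohort import MarkerSpec
            specs = [MarkerSpec(m) for m in cohort.markers if m != "EDSS_raw"]
        cohort.to_csv(out / "cohort_observations.csv", out / "cohort_covariates.csv")
        tables["cohort_observations"] = str(out / "cohort_observations.csv")
        tables["cohort_covariates"] = str(out / "cohort_covariates.csv")
    except Exception as e:  # noqa: BLE001
        _save_manifest()
        raise PipelineError(f"stage 'input' failed: {e}") from e

    # ---- stage: preprocess ---------------------------------------------
    try:
        abnormality = False
        model_cohort = cohort.subset_markers([s.name for s in specs])
        if config.use_quantile_scores:
            qmap = fit_quantile_map(model_cohort, specs)
            model_cohort = apply_quantile_map(qmap, model_cohort)
            qmap.to_json(out / "quantile_map.json")
            tables["quantile_map"] = str(out / "quantile_map.json")
            abnormality = True
    except Exception as e:  # noqa: BLE001
        _save_manifest()
        raise PipelineError(f"stage 'preprocess' failed: {e}") from e

    # ---- stage: fit ----------------------------------------------------
    try:
        fit_cfg = dataclasses.replace(config.fit, seed=config.seed)
        model = fit_progression_model(model_cohort, specs, fit_cfg,
                                      abnormality_oriented=abnormality)
        model_path = out / "model.json"
        model.save(model_path)
        metrics["timeline_span_years"] = timeline_span(model)
        metrics["converged"] = model.converged
        metrics["monotonicity_violation"] = model.monotonicity_violation()
        if truth is not None:
            common = model.shifts.index.intersection(truth.shifts.index)
            r = float(np.corrcoef(model.shifts[common], truth.shifts[common])[0, 1])
            metrics["shift_recovery_r"] = r
    except Exception as e:  # noqa: BLE001
        _save_manifest()
        raise PipelineError(f"stage 'fit' failed: {e}") from e

    # ---- stage: subgroups ----------------------------------------------
    try:
        assignments = {}
        for k in config.k_sd:
            a = classify_progressors(model.deltas, k_sd=k)
            assignments[k] = a
            p = out / f"subgroups_k{k:g}.csv"
            a.to_csv(p)
            tables[f"subgroups_k{k:g}"] = str(p)
            metrics[f"subgroup_fractions_k{k:g}"] = a.fractions().round(4).to_dict()
        primary = assignments[config.k_sd[0]]
        null_assign = null_classify(cohort, k_sd=config.k_sd[0])
        null_assign.to_csv(out / "subgroups_null.csv")
        tables["subgroups_null"] = str(out / "subgroups_null.csv")
        baseline_tbl = compare_baseline_characteristics(cohort.covariates, primary)
        _write_table(baseline_tbl, out / "baseline_characteristics.csv", config)
        tables["baseline_characteristics"] = str(out / "baseline_characteristics.csv")
    except Exception as e:  # noqa: BLE001
        _save_manifest()
        raise PipelineError(f"stage 'subgroups' failed: {e}") from e

    # ---- stage: outcomes -----------------------------------------------
    try:
        cox_rows = []
        for endpoint in config.endpoints:
            marker = "EDSS_raw" if endpoint == "EDSS" and "EDSS_raw" in cohort.markers else endpoint
            kind = "edss" if endpoint == "EDSS" else (
                "sdmt" if endpoint == "SDMT" else "percent")
            definition = CDPDefinition(name=f"CDP-{endpoint}", marker=marker, kind=kind,
                                       confirmation_months=6.0 if kind == "sdmt" else 3.0)
            ev = build_event_table(cohort, definition, primary)
            if ev.empty or ev["group"].nunique() < 2:
                warnings.warn(f"endpoint {endpoint}: not enough groups/data; skipped")
                continue
            _write_table(ev, out / f"events_{endpoint}.csv", config)
            tables[f"events_{endpoint}"] = str(out / f"events_{endpoint}.csv")
            cox = fit_cox(ev)
            cox.insert(0, "endpoint", definition.name)
            cox_rows.append(cox)
            km = km_and_logrank(ev)
            metrics[f"logrank_p_{endpoint}"] = km["logrank_p"]
            fig, ax = plt.subplots(figsize=(5, 4))
            for g, kmf in km["fitters"].items():
                kmf.plot_survival_function(ax=ax)
            ax.set_xlabel("months from baseline")
            ax.set_ylabel("progression-free fraction")
            ax.set_title(f"{definition.name} (log-rank p={km['logrank_p']:.2g})")
            fig.savefig(out / f"fig_km_{endpoint}.png", dpi=120)
            plt.close(fig)
            figures[f"km_{endpoint}"] = str(out / f"fig_km_{endpoint}.png")
        if cox_rows:
            cox_all = pd.concat(cox_rows, ignore_index=True)
            _write_table(cox_all, out / "cox_table.csv", config)
            tables["cox_table"] = str(out / "cox_table.csv")
    except Exception as e:  # noqa: BLE001
        _save_manifest()
        raise PipelineError(f"stage 'outcomes' failed: {e}") from e

    # ---- stage: figures ------------------------------------------------
    try:
        grid = model.default_grid(200)
        draws = sample_trajectories(model, config.n_realizations, grid, seed=config.seed)
        n_mark = len(model.markers)
        ncol = min(4, n_mark)
        nrow = int(np.ceil(n_mark / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                                 squeeze=False)
        for ax, m in zip(axes.ravel(), model.markers):
            ax.plot(grid, draws[m].T, color="steelblue", alpha=0.08, lw=0.7)
            ax.plot(grid, model.trajectory_mean(m, grid), color="navy", lw=2)
            ax.set_title(m, fontsize=9)
            ax.set_xlabel("disease time (y)", fontsize=8)
            ax.set_ylim(-0.05, 1.05)
        for ax in axes.ravel()[n_mark:]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(out / "fig_trajectories.png", dpi=120)
        plt.close(fig)
        figures["trajectories"] = str(out / "fig_trajectories.png")

        ordering = peak_rate_ordering(model, seed=config.seed)
        _write_table(ordering, out / "peak_rate_ordering.csv", config)
        tables["peak_rate_ordering"] = str(out / "peak_rate_ordering.csv")
        fig, ax = plt.subplots(figsize=(5, 0.5 * len(ordering) + 1.5))
        ypos = np.arange(len(ordering))[::-1]
        ax.errorbar(
            ordering["tau_peak_median"], ypos,
            xerr=np.vstack([
                ordering["tau_peak_median"] - ordering["tau_peak_lo"],
                ordering["tau_peak_hi"] - ordering["tau_peak_median"],
            ]),
            fmt="o", color="darkred", capsize=3,
        )
        ax.set_yticks(ypos)
        ax.set_yticklabels(ordering["marker"])
        ax.set_xlabel("stage at peak rate of change (y)")
        fig.tight_layout()
        fig.savefig(out / "fig_ordering.png", dpi=120)
        plt.close(fig)
        figures["ordering"] = str(out / "fig_ordering.png")

        pch = percent_change(model, seed=config.seed)
        _write_table(pch, out / "percent_change.csv", config)
        tables["percent_change"] = str(out / "percent_change.csv")
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(pch["marker"], pch["percent_change_mean"], color="seagreen")
        ax.scatter(pch["marker"], pch["percent_change_median"], marker="v",
                   color="darkgreen", zorder=3)
        ax.set_ylabel("% change over timeline")
        plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "fig_percent_change.png", dpi=120)
        plt.close(fig)
        figures["percent_change"] = str(out / "fig_percent_change.png")

        fig, ax = plt.subplots(figsize=(5, 3))
        deltas = model.deltas
        ax.hist(deltas, bins=30, color="slateblue", alpha=0.8)
        for k in config.k_sd:
            for sgn in (-1, 1):
                ax.axvline(deltas.mean() + sgn * k * deltas.std(ddof=1),
                           color="firebrick", ls="--", lw=1)
        ax.set_xlabel("reparametrization parameter delta (y)")
        fig.tight_layout()
        fig.savefig(out / "fig_shift_distribution.png", dpi=120)
        plt.close(fig)
        figures["shift_distribution"] = str(out / "fig_shift_distribution.png")
    except Exception as e:  # noqa: BLE001
        _save_manifest()
        raise PipelineError(f"stage 'figures' failed: {e}") from e

    _save_manifest()
    report = RunReport(
        out_dir=str(out),
        tables=tables,
        figures=figures,
        model_path=str(out / "model.json"),
        metrics=metrics,
    )
    report.to_json(out / "report.json")
    return report


def stage_external(
    trained_model_path,
    test_cohort_path,
    test_covariates_path=None,
    k_sd: float = 1.0,
    out_dir: str | None = None,
    recompute_cutoffs: bool = True,
    training_assignment=None,
    endpoints: list[str] | None = None,
):
    """Stage an external cohort with a trained model and analyse its subgroups.

    Population trajectories stay fixed; only the new subjects' shifts are
    inferred. Markers missing from the test cohort (e.g. a trial that never
    collected upper-limb timings) are tolerated; endpoints whose marker is
    absent are skipped with a notice. Cutoffs are recomputed on the test-set
    delta distribution by default (``recompute_cutoffs=False`` carries over a
    training assignment's mean/SD instead).
    """
    model = FittedProgressionModel.load(trained_model_path)
    cohort = LongitudinalCohort.from_csv(test_cohort_path, test_covariates_path)
    if cohort.observations.empty:
        raise ValueError("empty test cohort")
    unknown = [m for m in cohort.markers
               if m not in model.markers and m != "EDSS_raw"]
    usable = [m for m in cohort.markers if m in model.markers]
    if not usable:
        raise ValueError(
            f"no marker overlap between model ({model.markers}) and cohort; "
            f"offending markers: {unknown}"
        )
    staged = stage_new_subjects(model, cohort.subset_markers(usable))
    deltas = staged.set_index("subject_id")["delta"]
    if recompute_cutoffs or training_assignment is None:
        assignment = classify_progressors(deltas, k_sd=k_sd)
    else:
        mean, sd = training_assignment.mean, training_assignment.sd
        z = (deltas - mean) / sd
        label = pd.Series("G2", index=deltas.index, dtype=object)
        label[z > k_sd] = "G3"
        label[z < -k_sd] = "G1"
        from .subgroups import SubgroupAssignment
        assignment = SubgroupAssignment(
            table=pd.DataFrame({"subject_id": deltas.index,
                                "delta_years": deltas.values,
                                "label": label.values}),
            k_sd=k_sd, mean=mean, sd=sd,
        )
    results = {"staged": staged, "assignment": assignment, "events": {}, "cox": {}}
    for endpoint in endpoints or []:
        marker = "EDSS_raw" if endpoint == "EDSS" and "EDSS_raw" in cohort.markers else endpoint
        if marker not in cohort.markers:
            warnings.warn(f"endpoint {endpoint}: marker {marker!r} not in test cohort; skipped")
            continue
        kind = "edss" if endpoint == "EDSS" else ("sdmt" if endpoint == "SDMT" else "percent")
        definition = CDPDefinition(name=f"CDP-{endpoint}", marker=marker, kind=kind,
                                   confirmation_months=6.0 if kind == "sdmt" else 3.0)
        ev = build_event_table(cohort, definition, assignment)
        results["events"][endpoint] = ev
        if not ev.empty and ev["group"].nunique() >= 2 and ev["event"].sum() > 0:
            results["cox"][endpoint] = fit_cox(ev)
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        staged.to_csv(outp / "staged_subjects.csv", index=False)
        assignment.to_csv(outp / "staged_subgroups.csv")
        for endpoint, ev in results["events"].items():
            ev.to_csv(outp / f"events_{endpoint}.csv", index=False)
        for endpoint, cox in results["cox"].items():
            cox.to_csv(outp / f"cox_{endpoint}.csv", index=False)
    return results
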