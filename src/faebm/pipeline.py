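"""End-to-end orchestration: validate -> residualize -> fit -> order ->
cross-validate -> stage -> report.

`run_pipeline` executes every stage on an input biomarker table and
writes all artifacts (JSON/CSV plus a manifest) into a run directory;
two runs with the same config and seed produce identical numerical
outputs.  `render_reports` turns a run directory's matrices into the
standard figures.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .data_model import (
    canonical_region_set,
    fit_age_model,
    read_biomarker_table,
    residualize_age,
)
from .exceptions import FaebmError, SchemaError
from .mixtures import ConstraintConfig, fit_mixture_models, fits_to_frame
from .ordering import (
    EventOrdering,
    cross_validate,
    greedy_ascent,
    mcmc_sample,
    positional_variance,
)
from .plots import plot_pvd, plot_stage_proportions
from .staging import classify_by_stage, stage_proportions, stage_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    input_table: str
    output_dir: str
    region_mode: str = "combined"
    residualize: bool = False
    # mixture block
    mixture_bootstraps: int = 1000
    pooled: bool = True
    theta_bounds: tuple[float, float] = (0.0, 1.0)
    per_region_theta: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    # MCMC block
    mcmc_iterations: int = 100_000
    mcmc_burn_in: int = 10_000
    greedy_restarts: int = 10
    # cross-validation block
    cross_validation: bool = True
    cv_bootstraps: int = 10_000
    cv_restarts: int = 5
    # staging block
    stage_cutoff: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        if "theta_bounds" in raw:
            raw["theta_bounds"] = tuple(raw["theta_bounds"])
        if "per_region_theta" in raw:
            raw["per_region_theta"] = {
                k: tuple(v) for k, v in raw["per_region_theta"].items()
            }
        return cls(**raw)

    def constraint_config(self) -> ConstraintConfig:
        return ConstraintConfig(
            theta_bounds=self.theta_bounds,
            per_region_theta=self.per_region_theta,
        )


def _write_pvd_csv(pvd, path: Path) -> None:
    frame = pd.DataFrame(
        pvd.matrix,
        index=list(pvd.row_labels),
        columns=[f"pos_{p + 1}" for p in range(pvd.matrix.shape[1])],
    )
    frame.to_csv(path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage_name = "setup"
    try:
        t0 = time.perf_counter()
        region_set = canonical_region_set(config.region_mode)
        table = read_biomarker_table(config.input_table, region_set)

        if config.residualize:
            stage_name = "age_residualization"
            age_model = fit_age_model(table)
            table = residualize_age(table, age_model)
            age_model.slopes.rename("slope").to_frame().assign(
                intercept=age_model.intercepts,
                reference_age=age_model.reference_age,
            ).to_csv(out / "age_model.csv")
        timings["setup"] = time.perf_counter() - t0

        stage_name = "mixture_fitting"
        t0 = time.perf_counter()
        fits, control_model = fit_mixture_models(
            table,
            constraints=config.constraint_config(),
            B=config.mixture_bootstraps,
            pooled=config.pooled,
            seed=config.seed,
        )
        control_model.to_frame().to_csv(out / "control_model.csv")
        fits_to_frame(fits).to_csv(out / "mixture_fits.csv")
        timings["mixture_fitting"] = time.perf_counter() - t0

        stage_name = "ordering"
        t0 = time.perf_counter()
        patients = table.patients()
        init = greedy_ascent(
            patients, fits, restarts=config.greedy_restarts, seed=config.seed
        )
        posterior = mcmc_sample(
            patients,
            fits,
            init=init,
            n_iter=config.mcmc_iterations,
            burn_in=config.mcmc_burn_in,
            seed=config.seed,
        )
        pvd_mcmc = positional_variance(posterior)
        map_labels = posterior.map_ordering.region_labels(table.region_labels)
        (out / "map_ordering.json").write_text(
            json.dumps(
                {
                    "sequence": list(posterior.map_ordering.sequence),
                    "labels": list(map_labels),
                    "log_likelihood": posterior.map_log_likelihood,
                    "acceptance_rate": posterior.acceptance_rate,
                },
                indent=2,
            )
        )
        _write_pvd_csv(pvd_mcmc, out / "pvd_mcmc.csv")
        timings["ordering"] = time.perf_counter() - t0

        cv_result = None
        if config.cross_validation:
            stage_name = "cross_validation"
            t0 = time.perf_counter()
            cv_result = cross_validate(
                table,
                constraints=ConstraintConfig.weak(),
                B=config.cv_bootstraps,
                seed=config.seed,
                restarts=config.cv_restarts,
                pooled=config.pooled,
                reference=posterior.map_ordering,
            )
            _write_pvd_csv(cv_result.pvd, out / "pvd_cv.csv")
            timings["cross_validation"] = time.perf_counter() - t0

        stage_name = "staging"
        t0 = time.perf_counter()
        assignments = stage_table(table, posterior.map_ordering, fits)
        assignments.to_csv(out / "stages.csv", index=False)
        proportions = stage_proportions(assignments, len(region_set))
        proportions.to_csv(out / "stage_proportions.csv")
        sensitivity, specificity = classify_by_stage(
            assignments, cutoff=config.stage_cutoff
        )
        metrics = {
            "stage_cutoff": config.stage_cutoff,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "patients_at_stage_0": float(
                (
                    assignments.loc[assignments["group"] == "patient", "stage"]
                    == 0
                ).mean()
            ),
        }
        if cv_result is not None:
            metrics["cv_failed_replicates"] = cv_result.n_failed
            metrics["cv_mean_row_entropy"] = cv_result.pvd.mean_row_entropy()
            metrics["mcmc_mean_row_entropy"] = pvd_mcmc.mean_row_entropy()
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        timings["staging"] = time.perf_counter() - t0
    except FaebmError as exc:
        (out / "FAILED").write_text(f"stage {stage_name}: {exc}\n")
        raise FaebmError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "wall_times_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def render_reports(run_dir: str | Path) -> list[Path]:
    """Render PVD heatmap(s) and the stage-proportion bar chart from a
    completed run directory."""
    run_dir = Path(run_dir)
    written: list[Path] = []

    mcmc_path = run_dir / "pvd_mcmc.csv"
    if not mcmc_path.exists():
        raise FileNotFoundError(f"missing artifact: {mcmc_path}")
    pvds, titles = [_read_pvd(mcmc_path)], ["MCMC samples"]
    cv_path = run_dir / "pvd_cv.csv"
    if cv_path.exists():
        pvds.append(_read_pvd(cv_path))
        titles.append("Cross-validation")
    fig_path = run_dir / "pvd.png"
    plot_pvd(pvds, titles, path=fig_path)
    written.append(fig_path)

    prop_path = run_dir / "stage_proportions.csv"
    if not prop_path.exists():
        raise FileNotFoundError(f"missing artifact: {prop_path}")
    proportions = pd.read_csv(prop_path, index_col=0)
    bar_path = run_dir / "stage_proportions.png"
    plot_stage_proportions(proportions, path=bar_path)
    written.append(bar_path)
    return written


def _read_pvd(path: Path):
    from .ordering import PositionalVariance

    frame = pd.read_csv(path, index_col=0)
    n = frame.shape[0]
    return PositionalVariance(
        matrix=frame.to_numpy(dtype=float),
        reference=EventOrdering.identity(n),
        labels=tuple(frame.index),
    )
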