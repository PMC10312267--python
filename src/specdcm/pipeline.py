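"""End-to-end orchestration: simulate -> fit -> group -> compare.

A :class:`PipelineConfig` gathers every knob of the experiment in one
serializable structure (YAML or JSON). :func:`run_pipeline` executes the
stages in order, persists per-subject posteriors, group summaries and the
final quality report (JSON + CSV), and is fully deterministic given the
master seed. Stage failures are wrapped with the stage name; configuration
problems are raised before any computation starts.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import QualityReport, build_model_space, compare_datasets
from .group import SubjectData, fit_peb, reestimate_with_group_priors
from .model import (
    DcmParameterLayout,
    DcmPosterior,
    DcmPriors,
    InversionSettings,
    default_priors,
    schedule_power,
    variational_laplace,
)
from .simulate import (
    GroupDataset,
    SimulationConfig,
    generate_comparison_pair,
    make_block_schedule,
    write_dataset,
)
from .spectra import CrossSpectrum, FrequencyGrid, estimate_csd

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ConfigError",
    "DataError",
    "ConvergenceError",
    "run_pipeline",
    "fit_dataset",
    "posterior_to_dict",
    "posterior_from_dict",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the stage name is included."""


class ConfigError(PipelineError):
    pass


class DataError(PipelineError):
    pass


class ConvergenceError(PipelineError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Complete, explicit configuration of one comparison experiment."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mar_order: int = 8
    n_frequencies: int = 32
    f_max_hz: float = 0.25
    max_iterations: int = 64
    tolerance_nats: float = 0.01
    model_space_scheme: str = "leave-one-out"
    output_dir: str = "specdcm-output"
    seed: int = 0
    #: compare the rest dataset against an identical copy of itself
    #: (degenerate control: all differences must come out zero)
    self_comparison: bool = False

    def inversion_settings(self) -> InversionSettings:
        return InversionSettings(
            max_iterations=self.max_iterations, tolerance_nats=self.tolerance_nats
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        bad = (set(sim) - known_sim) | (set(data) - known)
        if bad:
            raise ConfigError(f"unknown configuration keys: {sorted(bad)}")
        try:
            return cls(simulation=SimulationConfig(**sim), **data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# posterior and spectrum (de)serialization — portable JSON
# ---------------------------------------------------------------------------

def posterior_to_dict(post: DcmPosterior) -> dict:
    return {
        "mean": post.mean.tolist(),
        "covariance": post.covariance.tolist(),
        "free_energy": post.free_energy,
        "accuracy": post.accuracy,
        "complexity": post.complexity,
        "n_iterations": post.n_iterations,
        "converged": post.converged,
        "log_precision": post.log_precision,
        "scale": post.scale,
        "layout": {"n_regions": post.layout.n_regions, "with_input": post.layout.with_input},
        "prior_mean": post.priors.mean.tolist(),
        "prior_covariance": post.priors.covariance.tolist(),
    }


def posterior_from_dict(d: dict) -> DcmPosterior:
    layout = DcmParameterLayout(**d["layout"])
    priors = DcmPriors(np.asarray(d["prior_mean"]), np.asarray(d["prior_covariance"]))
    return DcmPosterior(
        mean=np.asarray(d["mean"]),
        covariance=np.asarray(d["covariance"]),
        free_energy=d["free_energy"],
        accuracy=d["accuracy"],
        complexity=d["complexity"],
        n_iterations=d["n_iterations"],
        converged=d["converged"],
        layout=layout,
        priors=priors,
        log_precision=d["log_precision"],
        scale=d["scale"],
    )


def spectrum_to_dict(csd: CrossSpectrum) -> dict:
    return {
        "frequencies_hz": csd.grid.frequencies.tolist(),
        "real": csd.matrices.real.tolist(),
        "imag": csd.matrices.imag.tolist(),
    }


def spectrum_from_dict(d: dict) -> CrossSpectrum:
    grid = FrequencyGrid(np.asarray(d["frequencies_hz"]))
    mats = np.asarray(d["real"]) + 1j * np.asarray(d["imag"])
    return CrossSpectrum(grid, mats)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def fit_dataset(
    dataset: GroupDataset,
    config: PipelineConfig,
    with_input: bool,
) -> tuple[list[DcmPosterior], list[SubjectData]]:
    """Per-subject spectral features and DCM inversions for one dataset."""
    sim = config.simulation
    grid = FrequencyGrid.default(
        sim.duration_s, sim.tr_s, config.n_frequencies, config.f_max_hz
    )
    u_pow = None
    if with_input:
        schedule = make_block_schedule(sim)
        u_pow = schedule_power(schedule, sim.tr_s, grid)
    layout = DcmParameterLayout(sim.n_regions, with_input=with_input)
    priors = default_priors(layout)
    settings = config.inversion_settings()
    posteriors, handles = [], []
    for ts in dataset.subjects:
        csd = estimate_csd(ts, grid, config.mar_order)
        post = variational_laplace(
            csd, priors, layout, settings=settings, schedule_spectrum=u_pow
        )
        posteriors.append(post)
        handles.append(SubjectData(csd, u_pow))
    return posteriors, handles


def _stage(name: str, fn, *args, **kwargs):
    start = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        kind = DataError if isinstance(exc, (ValueError, OSError)) else PipelineError
        raise kind(f"stage '{name}' failed: {exc}") from exc
    logger.info("stage %-12s %6.1f s", name, time.perf_counter() - start)
    return result


def _save_posteriors(path: Path, posteriors: list[DcmPosterior]) -> None:
    path.write_text(
        json.dumps([posterior_to_dict(p) for p in posteriors], sort_keys=True)
    )


def run_pipeline(config: PipelineConfig) -> QualityReport:
    """Execute simulate -> fit -> reestimate -> PEB -> compare, persisting
    artifacts under ``config.output_dir``. Deterministic given the seed."""
    outdir = Path(config.output_dir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"cannot create output directory {outdir}: {exc}") from exc
    sim = dataclasses.replace(config.simulation, seed=config.seed)

    rest, task = _stage("simulate", generate_comparison_pair, sim)
    _stage("write-data", write_dataset, rest, outdir / "data", sim.seed)
    _stage("write-data", write_dataset, task, outdir / "data", sim.seed)

    cfg = dataclasses.replace(config, simulation=sim)
    rest_post, rest_data = _stage("fit-rest", fit_dataset, rest, cfg, False)
    if config.self_comparison:
        task_post, task_data = rest_post, rest_data
        label_b = "rest-copy"
    else:
        task_post, task_data = _stage("fit-task", fit_dataset, task, cfg, True)
        label_b = "task"
    n_rest = len(rest_post)

    combined = _stage(
        "reestimate",
        reestimate_with_group_priors,
        rest_post + task_post,
        rest_data + task_data,
        settings=config.inversion_settings(),
    )
    rest_post2, task_post2 = combined[:n_rest], combined[n_rest:]
    _save_posteriors(outdir / "posteriors_rest.json", rest_post2)
    _save_posteriors(outdir / "posteriors_task.json", task_post2)

    peb_rest = _stage("peb-rest", fit_peb, rest_post2)
    peb_task = _stage("peb-task", fit_peb, task_post2)

    space = _stage("model-space", build_model_space, sim.n_regions, config.model_space_scheme)
    report = _stage(
        "compare", compare_datasets, peb_rest, peb_task, space, "rest", label_b
    )

    n_unconverged = sum(not p.converged for p in combined)
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "report": report.to_dict(),
        "group": {
            label: {
                "beta_mean": peb.beta_mean.tolist(),
                "free_energy": peb.free_energy,
                "gamma": peb.gamma,
                "param_names": list(peb.param_names),
            }
            for label, peb in (("rest", peb_rest), ("task", peb_task))
        },
        "n_unconverged_subjects": n_unconverged,
    }
    (outdir / "report.json").write_text(json.dumps(payload, sort_keys=True, indent=1))

    rows = [
        {
            "dataset": ix.dataset_label,
            "parameter_certainty": ix.parameter_certainty,
            "info_gain_parameters": ix.info_gain_parameters,
            "info_gain_models": ix.info_gain_models,
        }
        for ix in report.indices
    ]
    pd.DataFrame(rows).to_csv(outdir / "indices.csv", index=False)
    means = pd.DataFrame(
        {
            "parameter": peb_rest.param_names,
            "rest": peb_rest.beta_mean,
            "task": peb_task.beta_mean,
        }
    )
    means.to_csv(outdir / "group_means.csv", index=False)
    return report
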