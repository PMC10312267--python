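"""Synthetic rest/task BOLD generator with known ground-truth connectivity.

This module emulates the study conditions the rest of the package is
validated against: five coupled neural populations with first-order linear
dynamics, power-law endogenous fluctuations, a block-design exogenous input
driving one region in the task condition, haemodynamic convolution, additive
observation noise, and between-subject variability of the coupling rates.

The default configuration mirrors a fast-TR acquisition (TR = 0.72 s, run
length 207 s, 5 regions, 50 subjects) with a block schedule of an 8 s
countdown followed by cycles of 20 s stimulus, 3 s response and 15 s
fixation. Note the schedule (8 + 5*38 = 198 s) and the run length (207 s)
are configured independently: the tail of the run simply carries no input.

Neural and observation noise are stationary Gaussian processes with
one-sided power spectral density ``amplitude * f**(-exponent)`` (signal
units squared per Hz), generated by spectral synthesis: shape the Fourier
amplitudes, draw random phases, inverse transform, with the zero-frequency
bin forced to zero.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.signal import fftconvolve

from .connectivity import (
    STABILITY_MARGIN_HZ,
    ConnectivityGraph,
    default_template,
    effective_coupling,
    is_stable,
    stabilize,
)
from .hemo import hrf_kernel

__all__ = [
    "SimulationConfig",
    "RegionTimeseries",
    "GroupDataset",
    "sample_group_parameters",
    "make_block_schedule",
    "simulate_bold",
    "generate_comparison_pair",
    "powerlaw_noise",
    "write_dataset",
    "read_dataset",
    "default_region_labels",
]

#: Integration substeps per TR for the exact (matrix-exponential)
#: discretization of the neural ODE.
UPSAMPLE = 8

#: Redraws allowed per subject before stability is enforced by shifting
#: the self-connections.
MAX_STABILITY_RETRIES = 20


def default_region_labels(n_regions: int) -> list[str]:
    """Region labels; the 5-region default names the emulated network nodes
    (precuneus, superior temporal sulcus, angular gyrus, temporal pole,
    fusiform gyrus)."""
    if n_regions == 5:
        return ["PCu", "STS", "AnG", "TP", "FG"]
    return [f"R{i + 1}" for i in range(n_regions)]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the paired rest/task generator.

    Durations are seconds; coupling deviations and rates are Hz. The
    between-subject standard deviation defaults to 0.0625 Hz, one standard
    deviation of the shrinkage prior N(0, 1/64) used by the model.
    """

    n_regions: int = 5
    n_subjects: int = 50
    tr_s: float = 0.72
    duration_s: float = 207.0
    neural_noise_amplitude: float = 0.01
    neural_noise_exponent: float = 1.0
    observation_noise_amplitude: float = 0.02
    observation_noise_exponent: float = 0.0
    between_subject_sd: float = 0.0625
    coupling_scale_rest: float = 1.0
    coupling_scale_task: float = 2.0
    countdown_s: float = 8.0
    block_s: float = 20.0
    response_s: float = 3.0
    fixation_s: float = 15.0
    n_blocks: int = 5
    drive_region: int = -1
    driving_weight: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for name in ("duration_s", "countdown_s", "block_s", "response_s", "fixation_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.between_subject_sd < 0:
            raise ValueError("between_subject_sd must be >= 0")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.duration_s / self.tr_s))


@dataclass(frozen=True)
class RegionTimeseries:
    """One subject's time-by-region BOLD matrix with acquisition metadata."""

    values: np.ndarray
    tr_s: float
    subject_id: str
    condition: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError(f"values must be time x regions with >= 2 regions, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("timeseries contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GroupDataset:
    """An ordered collection of subjects plus the generative ground truth."""

    subjects: tuple[RegionTimeseries, ...]
    truth: tuple[ConnectivityGraph, ...]
    condition: str

    def __post_init__(self) -> None:
        subjects = tuple(self.subjects)
        truth = tuple(self.truth)
        if len(subjects) != len(truth):
            raise ValueError("one truth graph per subject required")
        shapes = {(s.n_samples, s.n_regions, s.tr_s) for s in subjects}
        if len(shapes) > 1:
            raise ValueError("all subjects must share n_regions, tr_s and duration")
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "truth", truth)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def sample_group_parameters(
    template: ConnectivityGraph,
    n_subjects: int,
    between_subject_sd: float,
    seed: int,
) -> list[ConnectivityGraph]:
    """Draw per-subject graphs around a template.

    Each subject's between-region rates are the template's plus independent
    Gaussian deviations of standard deviation ``between_subject_sd`` (Hz);
    self log-scalings and driving weights are inherited. Draws violating the
    stability margin are redrawn up to MAX_STABILITY_RETRIES times and, as a
    last resort, shifted to stability through the self-connections.
    """
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be >= 0")
    if not is_stable(template, margin_hz=abs(STABILITY_MARGIN_HZ)):
        raise ValueError("template graph violates the stability margin")
    n = template.n_regions
    mask = 1.0 - np.eye(n)
    rng = np.random.default_rng(seed)
    graphs: list[ConnectivityGraph] = []
    for s in range(n_subjects):
        graph = None
        for _ in range(MAX_STABILITY_RETRIES):
            off = template.off_diagonal + rng.normal(0.0, between_subject_sd, (n, n)) * mask
            cand = replace(template, off_diagonal=off)
            if is_stable(cand, margin_hz=abs(STABILITY_MARGIN_HZ)):
                graph = cand
                break
        if graph is None:
            graph = stabilize(cand)
            if not is_stable(graph):
                raise RuntimeError(f"could not stabilize subject {s} after redraws and shift")
        graphs.append(graph)
    return graphs


def make_block_schedule(config: SimulationConfig) -> np.ndarray:
    """Boxcar input u(t) sampled every TR over the full run.

    Zero during the countdown, response and fixation intervals and during
    any tail beyond the scheduled blocks; one during the ``n_blocks``
    stimulus blocks of length ``block_s``.
    """
    t = np.arange(config.n_samples) * config.tr_s
    u = np.zeros(config.n_samples)
    cycle = config.block_s + config.response_s + config.fixation_s
    for b in range(config.n_blocks):
        start = config.countdown_s + b * cycle
        u[(t >= start) & (t < start + config.block_s)] = 1.0
    return u


def powerlaw_noise(
    n_samples: int,
    dt_s: float,
    amplitude: float,
    exponent: float,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Stationary Gaussian series with one-sided PSD amplitude * f**(-exponent).

    Spectral synthesis: complex-Gaussian Fourier coefficients are scaled so
    that the expected periodogram (density convention, sampling rate 1/dt)
    equals the target PSD; the zero-frequency bin is zero, so every series is
    exactly mean-free in expectation and has no DC component.
    Returns an array of shape (n_samples, n_series).
    """
    if amplitude == 0.0:
        return np.zeros((n_samples, n_series))
    fs = 1.0 / dt_s
    freqs = np.fft.rfftfreq(n_samples, d=dt_s)
    target = np.zeros_like(freqs)
    target[1:] = amplitude * freqs[1:] ** (-exponent)
    # E|V_k|^2 = S_k * fs * N / 2 makes the one-sided periodogram match S.
    sigma = np.sqrt(target * fs * n_samples / 2.0)
    shape = (freqs.size, n_series)
    coef = sigma[:, None] * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)
    coef[0] = 0.0
    if n_samples % 2 == 0:
        coef[-1] = coef[-1].real * np.sqrt(2.0)
    return np.fft.irfft(coef, n=n_samples, axis=0)


def simulate_bold(
    graph: ConnectivityGraph,
    schedule: np.ndarray,
    config: SimulationConfig,
    seed: int,
    subject_id: str = "sub-00",
    condition: str = "rest",
) -> RegionTimeseries:
    """Integrate the neural ODE and observe it through the haemodynamic model.

    dz/dt = A_eff z + C u(t) + v(t), with v power-law endogenous noise, is
    discretized exactly (matrix exponential, zero-order hold) on a grid of
    TR/8, convolved with the canonical kernel, downsampled to the TR, and
    corrupted with power-law observation noise. Each region is mean
    corrected. Deterministic given the seed.
    """
    if not is_stable(graph):
        raise ValueError("graph must be stable (all eigenvalue real parts < 0)")
    n_samples = config.n_samples
    if schedule.shape != (n_samples,):
        raise ValueError(
            f"schedule length {schedule.shape} inconsistent with config ({n_samples} samples)"
        )
    n = graph.n_regions
    dt = config.tr_s / UPSAMPLE
    n_fine = n_samples * UPSAMPLE
    rng = np.random.default_rng(seed)

    a_eff = effective_coupling(graph)
    propagator = expm(a_eff * dt)
    # B = A^-1 (e^{A dt} - I): exact response to piecewise-constant input
    b_mat = np.linalg.solve(a_eff, propagator - np.eye(n))

    u_fine = np.repeat(schedule, UPSAMPLE)
    drive = u_fine[:, None] * graph.driving_weights[None, :]
    noise = powerlaw_noise(
        n_fine, dt, config.neural_noise_amplitude, config.neural_noise_exponent, rng, n
    )
    forcing = (drive + noise) @ b_mat.T

    z = np.zeros((n_fine, n))
    state = np.zeros(n)
    for k in range(n_fine):
        state = propagator @ state + forcing[k]
        z[k] = state
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite neural states during integration")

    kernel = hrf_kernel(dt)
    bold_fine = fftconvolve(z, kernel[:, None], axes=0)[:n_fine] * dt
    bold = bold_fine[UPSAMPLE - 1 :: UPSAMPLE][:n_samples]

    obs = powerlaw_noise(
        n_samples,
        config.tr_s,
        config.observation_noise_amplitude,
        config.observation_noise_exponent,
        rng,
        n,
    )
    y = bold + obs
    y = y - y.mean(axis=0, keepdims=True)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite BOLD output")
    return RegionTimeseries(values=y, tr_s=config.tr_s, subject_id=subject_id, condition=condition)


def generate_comparison_pair(
    config: SimulationConfig,
    template: ConnectivityGraph | None = None,
) -> tuple[GroupDataset, GroupDataset]:
    """Generate matched rest-like and task-like group datasets.

    The same subjects are simulated twice: at rest with the template
    couplings scaled by ``coupling_scale_rest`` and no exogenous input, and
    under the task with the template scaled by ``coupling_scale_task`` and
    the block schedule driving one region through the C weights. The
    condition scaling applies to the group-mean (template) couplings only;
    each subject's Gaussian deviations around the template are drawn once
    and shared between conditions, so the between-subject variability is
    matched across conditions and only the mean coupling strength differs.
    Ground-truth graphs are retained per subject.
    """
    if template is None:
        template = default_template(
            config.n_regions,
            driving_weight=config.driving_weight,
            drive_region=config.drive_region,
        )
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.n_subjects + 1)
    rest_template = stabilize(
        replace(
            template,
            off_diagonal=template.off_diagonal * config.coupling_scale_rest,
            driving_weights=np.zeros(config.n_regions),
        )
    )
    task_template = stabilize(
        replace(template, off_diagonal=template.off_diagonal * config.coupling_scale_task)
    )
    # identical seed: both conditions share each subject's coupling deviations
    rest_graphs = sample_group_parameters(
        rest_template, config.n_subjects, config.between_subject_sd, seed=int(seeds[0])
    )
    task_graphs = sample_group_parameters(
        task_template, config.n_subjects, config.between_subject_sd, seed=int(seeds[0])
    )
    schedule = make_block_schedule(config)
    silence = np.zeros_like(schedule)

    rest_subj, rest_truth, task_subj, task_truth = [], [], [], []
    for s, (g_rest, g_task) in enumerate(zip(rest_graphs, task_graphs)):
        sid = f"sub-{s + 1:02d}"
        rest_truth.append(g_rest)
        task_truth.append(g_task)
        rest_subj.append(
            simulate_bold(g_rest, silence, config, int(seeds[1 + 2 * s]), sid, "rest")
        )
        task_subj.append(
            simulate_bold(g_task, schedule, config, int(seeds[2 + 2 * s]), sid, "task")
        )
    rest = GroupDataset(tuple(rest_subj), tuple(rest_truth), "rest")
    task = GroupDataset(tuple(task_subj), tuple(task_truth), "task")
    return rest, task


# ---------------------------------------------------------------------------
# dataset I/O: one TSV per subject + JSON sidecar, manifest + truth as JSON
# ---------------------------------------------------------------------------

def _graph_to_dict(graph: ConnectivityGraph) -> dict:
    return {
        "off_diagonal": graph.off_diagonal.tolist(),
        "self_log_scale": graph.self_log_scale.tolist(),
        "driving_weights": graph.driving_weights.tolist(),
    }


def _graph_from_dict(d: dict) -> ConnectivityGraph:
    return ConnectivityGraph(
        np.asarray(d["off_diagonal"]),
        np.asarray(d["self_log_scale"]),
        np.asarray(d["driving_weights"]),
    )


def write_dataset(dataset: GroupDataset, outdir: str | Path, seed: int | None = None) -> Path:
    """Persist a dataset as per-subject TSVs with JSON sidecars and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = default_region_labels(dataset.subjects[0].n_regions)
    members = []
    for ts in dataset.subjects:
        stem = f"{ts.subject_id}_{ts.condition}"
        pd.DataFrame(ts.values, columns=labels).to_csv(
            outdir / f"{stem}.tsv", sep="\t", index=False, float_format="%.8g"
        )
        sidecar = {
            "subject_id": ts.subject_id,
            "condition": ts.condition,
            "tr_s": ts.tr_s,
            "seed": seed,
        }
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        members.append(stem)
    truth_file = f"truth_{dataset.condition}.json"
    (outdir / truth_file).write_text(
        json.dumps([_graph_to_dict(g) for g in dataset.truth], sort_keys=True)
    )
    manifest = {
        "condition": dataset.condition,
        "members": members,
        "truth_file": truth_file,
    }
    manifest_path = outdir / f"manifest_{dataset.condition}.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_dataset(manifest_path: str | Path) -> GroupDataset:
    """Load a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    subjects, truth = [], []
    for stem in manifest["members"]:
        sidecar = json.loads((root / f"{stem}.json").read_text())
        frame = pd.read_csv(root / f"{stem}.tsv", sep="\t")
        subjects.append(
            RegionTimeseries(
                frame.to_numpy(),
                tr_s=sidecar["tr_s"],
                subject_id=sidecar["subject_id"],
                condition=sidecar["condition"],
            )
        )
    for d in json.loads((root / manifest["truth_file"]).read_text()):
        truth.append(_graph_from_dict(d))
    return GroupDataset(tuple(subjects), tuple(truth), manifest["condition"])
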