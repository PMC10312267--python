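"""Directed effective-connectivity graphs for linear neural-mass dynamics.

A :class:`ConnectivityGraph` holds the three ingredients of the neural model
shared by the simulator and the spectral DCM:

* ``off_diagonal`` — between-region coupling rates in Hz; entry ``(i, j)``
  is the influence of region ``j`` on region ``i`` (zero on the diagonal);
* ``self_log_scale`` — unitless log-scaling parameters of the inhibitory
  self-connections; a region's self-coupling rate is ``-0.5 * exp(s)`` Hz,
  so the default rate at ``s = 0`` is -0.5 Hz;
* ``driving_weights`` — the C vector, Hz per unit of exogenous input.

The effective coupling matrix assembled from these must have all eigenvalue
real parts strictly negative, otherwise the neural dynamics diverge.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SELF_RATE_HZ",
    "STABILITY_MARGIN_HZ",
    "ConnectivityGraph",
    "effective_coupling",
    "is_stable",
    "stabilize",
    "default_template",
]

#: Baseline self-inhibition rate (Hz) at zero log-scaling.
SELF_RATE_HZ = -0.5

#: Largest admissible real part of an eigenvalue of the effective coupling
#: matrix (Hz). Graphs whose slowest mode decays slower than this are
#: treated as unstable and shifted.
STABILITY_MARGIN_HZ = -0.05


@dataclass(frozen=True)
class ConnectivityGraph:
    """Effective-connectivity parameters of one subject's neural network."""

    off_diagonal: np.ndarray
    self_log_scale: np.ndarray
    driving_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        off = np.asarray(self.off_diagonal, dtype=float)
        if off.ndim != 2 or off.shape[0] != off.shape[1]:
            raise ValueError(f"off_diagonal must be square, got shape {off.shape}")
        n = off.shape[0]
        if np.any(np.diag(off) != 0.0):
            raise ValueError(
                "off_diagonal must have a zero diagonal; self-coupling lives in "
                "self_log_scale"
            )
        s = np.asarray(self.self_log_scale, dtype=float).reshape(-1)
        if s.size != n:
            raise ValueError(f"self_log_scale has {s.size} entries, expected {n}")
        c = self.driving_weights
        c = np.zeros(n) if c is None else np.asarray(c, dtype=float).reshape(-1)
        if c.size != n:
            raise ValueError(f"driving_weights has {c.size} entries, expected {n}")
        if not (np.all(np.isfinite(off)) and np.all(np.isfinite(s)) and np.all(np.isfinite(c))):
            raise ValueError("graph parameters must be finite")
        object.__setattr__(self, "off_diagonal", off)
        object.__setattr__(self, "self_log_scale", s)
        object.__setattr__(self, "driving_weights", c)

    @property
    def n_regions(self) -> int:
        return self.off_diagonal.shape[0]


def effective_coupling(graph: ConnectivityGraph) -> np.ndarray:
    """Assemble the effective coupling matrix A_eff in Hz.

    Off-diagonal entries pass through unchanged; diagonal entry ``i`` is
    ``-0.5 * exp(self_log_scale[i])``, i.e. -0.5 Hz at zero log-scaling.
    """
    a = graph.off_diagonal.copy()
    np.fill_diagonal(a, SELF_RATE_HZ * np.exp(graph.self_log_scale))
    return a


def max_real_eigenvalue(graph: ConnectivityGraph) -> float:
    return float(np.max(np.linalg.eigvals(effective_coupling(graph)).real))


def is_stable(graph: ConnectivityGraph, margin_hz: float = 0.0) -> bool:
    """True when every eigenvalue real part of A_eff lies below ``-margin``."""
    return max_real_eigenvalue(graph) < -abs(margin_hz)


def stabilize(graph: ConnectivityGraph) -> ConnectivityGraph:
    """Shift an (near-)unstable graph to stability via the self-connections.

    If the largest eigenvalue real part of A_eff is >= STABILITY_MARGIN_HZ,
    subtract ``(max_real + 0.1) I`` from A_eff by deepening every region's
    self-inhibition, re-expressed through the log-scaling parameters.
    """
    mre = max_real_eigenvalue(graph)
    if mre < STABILITY_MARGIN_HZ:
        return graph
    shift = mre + 0.1
    current = -SELF_RATE_HZ * np.exp(graph.self_log_scale)  # 0.5 e^s, positive
    new_scale = np.log((current + shift) / -SELF_RATE_HZ)
    return replace(graph, self_log_scale=new_scale)


def default_template(n_regions: int = 5, driving_weight: float = 0.3,
                     drive_region: int = -1) -> ConnectivityGraph:
    """A fixed, stable coupling template used as the group-level truth.

    For five regions the off-diagonal rates lie in ±[0.2, 0.4] Hz with mixed
    excitation/inhibition; self log-scalings are zero (-0.5 Hz rates) and the
    exogenous drive enters the last region by default (the fusiform node in
    the emulated network). For other sizes a deterministic banded pattern of
    the same magnitude is produced.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if n_regions == 5:
        off = np.array(
            [
                [0.00, 0.25, -0.30, 0.00, 0.20],
                [0.30, 0.00, 0.25, -0.20, 0.00],
                [-0.25, 0.20, 0.00, 0.30, -0.20],
                [0.00, -0.25, 0.30, 0.00, 0.25],
                [0.20, 0.00, -0.20, 0.25, 0.00],
            ]
        )
    else:
        off = np.zeros((n_regions, n_regions))
        for i in range(n_regions):
            j = (i + 1) % n_regions
            k = (i - 1) % n_regions
            off[i, j] = 0.3 if i % 2 == 0 else -0.25
            off[i, k] = 0.2 if j % 2 == 0 else -0.3
        np.fill_diagonal(off, 0.0)
    weights = np.zeros(n_regions)
    weights[drive_region] = driving_weight
    graph = ConnectivityGraph(off, np.zeros(n_regions), weights)
    return stabilize(graph)
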