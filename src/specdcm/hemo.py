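"""Canonical haemodynamic response kernel and its frequency response.

The forward model treats the mapping from neural states to BOLD as linear
convolution with a fixed double-gamma kernel (response peak 6 s, undershoot
peak 16 s, undershoot ratio 1/6), peak-normalized to 1. The same kernel is
used by the simulator and by the spectral observation model, which keeps the
forward and inverse problems consistent. Kernel shape parameters are module
constants rather than estimated quantities.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["hrf_kernel", "hrf_transfer", "HRF_DURATION_S"]

#: Support of the kernel in seconds; the double-gamma is negligible beyond.
HRF_DURATION_S = 32.0

_PEAK_DELAY_S = 6.0
_UNDERSHOOT_DELAY_S = 16.0
_UNDERSHOOT_RATIO = 6.0
_DISPERSION_S = 1.0


def hrf_kernel(dt_s: float) -> np.ndarray:
    """Sample the double-gamma kernel on a grid of spacing ``dt_s`` seconds.

    Returns the kernel values at t = 0, dt, 2 dt, ... up to HRF_DURATION_S,
    normalized to unit peak.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, HRF_DURATION_S, dt_s)
    peak = stats.gamma.pdf(t, _PEAK_DELAY_S / _DISPERSION_S, scale=_DISPERSION_S)
    under = stats.gamma.pdf(t, _UNDERSHOOT_DELAY_S / _DISPERSION_S, scale=_DISPERSION_S)
    k = peak - under / _UNDERSHOOT_RATIO
    return k / np.max(np.abs(k))


def hrf_transfer(frequencies_hz: np.ndarray, dt_s: float = 0.09) -> np.ndarray:
    """Continuous-time frequency response h(f) of the kernel.

    Approximates the Fourier integral by a Riemann sum over the sampled
    kernel: h(f) = sum_t k(t) exp(-2 pi i f t) dt. ``dt_s`` controls the
    quadrature resolution only.
    """
    f = np.atleast_1d(np.asarray(frequencies_hz, dtype=float))
    k = hrf_kernel(dt_s)
    t = np.arange(k.size) * dt_s
    return (k[None, :] * np.exp(-2j * np.pi * f[:, None] * t[None, :])).sum(axis=1) * dt_s
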