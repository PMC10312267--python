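"""Cross-spectral density estimation from region timeseries.

The spectral DCM is fitted to cross-spectral densities rather than to the
timeseries themselves. Following common practice the CSD is estimated
parametrically: a multivariate autoregression (default order 8) is fitted by
least squares to the detrended series and converted to a spectral matrix
through its transfer function,

    S(f) = 2 tr H(f) Sigma H(f)^H,   H(f) = (I - sum_p A_p e^{-2 pi i f p tr})^{-1},

the one-sided density convention in which the integral of the diagonal over
(0, Nyquist] approximates the series variance. Series are mean- and
linear-trend-corrected before fitting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .simulate import RegionTimeseries

__all__ = [
    "FrequencyGrid",
    "CrossSpectrum",
    "MarModel",
    "fit_mar",
    "mar_to_csd",
    "estimate_csd",
    "DEFAULT_MAR_ORDER",
]

DEFAULT_MAR_ORDER = 8
_HERMITIAN_TOL = 1e-10


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies (Hz), bounded by Nyquist."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float).reshape(-1)
        if f.size == 0:
            raise ValueError("empty frequency grid")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing and positive")
        object.__setattr__(self, "frequencies", f)

    @property
    def size(self) -> int:
        return self.frequencies.size

    @classmethod
    def default(
        cls,
        duration_s: float,
        tr_s: float,
        n_points: int = 32,
        f_max_hz: float = 0.25,
        f_min_hz: float = 1.0 / 64.0,
    ) -> "FrequencyGrid":
        """Logarithmic grid over the band the observation model is
        informative for.

        Runs from max(1/window-length, ``f_min_hz``) to min(``f_max_hz``,
        Nyquist). The floor (default 1/64 Hz) keeps the grid above the
        band a short-window autoregressive spectral estimate can resolve:
        below a few cycles per run the estimated spectra are strongly
        biased and would corrupt the fit.
        """
        nyquist = 0.5 / tr_s
        lo = max(1.0 / duration_s, f_min_hz)
        hi = min(f_max_hz, nyquist)
        if hi <= lo:
            raise ValueError("window too short for the requested band")
        return cls(np.geomspace(lo, hi, n_points))

    def validate_for(self, tr_s: float) -> None:
        nyquist = 0.5 / tr_s
        if self.frequencies[-1] > nyquist + 1e-12:
            raise ValueError(
                f"grid extends to {self.frequencies[-1]:.4g} Hz beyond Nyquist {nyquist:.4g} Hz"
            )


@dataclass(frozen=True)
class CrossSpectrum:
    """Hermitian complex region-by-region matrix per grid frequency.

    ``effective_dof`` records how many independent numbers the spectral
    estimate actually carries (for a parametric estimate, the parameter
    count of the autoregression it derives from). Downstream likelihoods
    use it to avoid counting the same information once per grid point.
    """

    grid: FrequencyGrid
    matrices: np.ndarray  # (n_freq, n_regions, n_regions) complex
    effective_dof: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=complex)
        if m.ndim != 3 or m.shape[0] != self.grid.size or m.shape[1] != m.shape[2]:
            raise ValueError(f"matrices must be (n_freq, n, n), got {m.shape}")
        herm_err = np.max(np.abs(m - m.conj().transpose(0, 2, 1)))
        diag = np.diagonal(m, axis1=1, axis2=2)
        if herm_err > 1e-6:
            raise ValueError(f"matrices not Hermitian (max asymmetry {herm_err:.3e})")
        if np.min(diag.real) < -_HERMITIAN_TOL:
            raise ValueError("negative diagonal power")
        object.__setattr__(self, "matrices", m)

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


@dataclass(frozen=True)
class MarModel:
    """Least-squares multivariate autoregression of a stated order."""

    coefficients: np.ndarray  # (order, n, n); lag-p block maps y[t-p] -> y[t]
    noise_covariance: np.ndarray  # (n, n) innovation covariance
    order: int
    tr_s: float


def _detrended(values: np.ndarray) -> np.ndarray:
    return detrend(np.asarray(values, dtype=float), axis=0, type="linear")


def fit_mar(ts: RegionTimeseries, order: int = DEFAULT_MAR_ORDER) -> MarModel:
    """Fit a multivariate autoregression to a subject's detrended series.

    Order 0 performs no regression and returns the sample covariance of the
    detrended data as the innovation covariance.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    y = _detrended(ts.values)
    t, n = y.shape
    if t <= order * n:
        raise ValueError(f"{t} samples insufficient for order {order} with {n} regions")
    if order == 0:
        cov = y.T @ y / t
        return MarModel(np.zeros((0, n, n)), 0.5 * (cov + cov.T), 0, ts.tr_s)
    rows = t - order
    design = np.empty((rows, order * n))
    for p in range(order):
        design[:, p * n : (p + 1) * n] = y[order - 1 - p : t - 1 - p]
    target = y[order:]
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient autoregression design (rank {rank} < {design.shape[1]}); "
            "try a lower order"
        )
    resid = target - design @ coef
    cov = resid.T @ resid / rows
    a = coef.reshape(order, n, n).transpose(0, 2, 1)  # lag blocks acting on column vectors
    return MarModel(a, 0.5 * (cov + cov.T), order, ts.tr_s)


def mar_to_csd(mar: MarModel, grid: FrequencyGrid, tr_s: float | None = None) -> CrossSpectrum:
    """Evaluate the MAR spectral matrix H Sigma H^H on a frequency grid."""
    tr = mar.tr_s if tr_s is None else tr_s
    grid.validate_for(tr)
    f = grid.frequencies
    n = mar.noise_covariance.shape[0]
    eye = np.eye(n)
    mats = np.empty((f.size, n, n), dtype=complex)
    for k, freq in enumerate(f):
        acc = eye.astype(complex).copy()
        for p in range(mar.order):
            acc -= mar.coefficients[p] * np.exp(-2j * np.pi * freq * (p + 1) * tr)
        h = np.linalg.inv(acc)
        mats[k] = 2.0 * tr * h @ mar.noise_covariance @ h.conj().T
    mats = 0.5 * (mats + mats.conj().transpose(0, 2, 1))
    # clip round-off negatives on the diagonal
    idx = np.arange(n)
    diag = mats[:, idx, idx].real
    mats[:, idx, idx] = np.clip(diag, 0.0, None)
    dof = mar.order * n**2 + n * (n + 1) // 2
    return CrossSpectrum(grid, mats, effective_dof=float(dof))


def estimate_csd(
    ts: RegionTimeseries,
    grid: FrequencyGrid | None = None,
    order: int = DEFAULT_MAR_ORDER,
) -> CrossSpectrum:
    """Convenience wrapper: detrend, fit the MAR, evaluate the CSD."""
    if grid is None:
        grid = FrequencyGrid.default(ts.n_samples * ts.tr_s, ts.tr_s)
    return mar_to_csd(fit_mar(ts, order), grid)
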