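"""Spectral DCM: generative model of cross-spectra and its Bayesian inversion.

The within-subject generative model maps effective-connectivity parameters
to a predicted cross-spectral density,

    G_y(f) = K(f) G_v(f) K(f)^H + G_e(f),
    K(f)   = h(f) (2 pi i f I - A_eff)^{-1},

where ``A_eff`` is the effective coupling matrix (between-region rates in Hz
off the diagonal, ``-0.5 exp(s_i)`` Hz on it), ``h(f)`` the fixed canonical
haemodynamic frequency response, ``G_v`` the power-law spectrum of the
endogenous neural fluctuations (plus deterministic input power routed
through the C weights under a task), and ``G_e`` the power-law observation
noise spectrum. The haemodynamic kernel is a fixed constant of the model,
not an estimated quantity.

Inversion is by variational Laplace: Gauss-Newton ascent, with
Levenberg-Marquardt damping, on the variational free energy of a Gaussian
observation model over the stacked real and imaginary parts of the
cross-spectra, with a single estimated log-precision hyperparameter on the
residuals. The result is a Gaussian posterior over the parameters together
with the free energy and its accuracy/complexity decomposition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._gaussian import gaussian_kl, logdet_pd, sym
from .connectivity import SELF_RATE_HZ, ConnectivityGraph, effective_coupling
from .hemo import hrf_transfer
from .spectra import CrossSpectrum, FrequencyGrid

__all__ = [
    "DcmParameterLayout",
    "DcmParameters",
    "DcmPriors",
    "DcmPosterior",
    "InversionSettings",
    "effective_coupling",
    "predict_csd",
    "predict_csd_jacobian",
    "variational_laplace",
    "free_energy_decomposition",
    "csd_to_vector",
    "schedule_power",
    "default_priors",
]

logger = logging.getLogger(__name__)

# Operating point of the spectral (noise) parameters: amplitudes are
# log-scaled around these bases and exponents are additive deviations.
NEURAL_AMP_BASE = 0.01
NEURAL_EXP_BASE = 1.0
OBS_AMP_BASE = 0.02
OBS_EXP_BASE = 0.0

# Prior variances (shrinkage priors, zero mean throughout).
PRIOR_VAR_A = 1.0 / 64.0
PRIOR_VAR_SELF = 1.0 / 256.0
PRIOR_VAR_C = 1.0 / 64.0
PRIOR_VAR_SPECTRAL = 1.0 / 64.0


@dataclass(frozen=True)
class DcmParameterLayout:
    """Fixed vectorization order of the DCM parameters.

    Row-major between-region A entries first (n(n-1) of them, skipping the
    diagonal), then the n self log-scalings, then — when an exogenous input
    is modelled — the n driving weights C, then four spectral parameters:
    neural log-amplitude, neural exponent deviation, observation
    log-amplitude, observation exponent deviation.
    """

    n_regions: int
    with_input: bool = False

    @property
    def off_diagonal_pairs(self) -> list[tuple[int, int]]:
        n = self.n_regions
        return [(i, j) for i in range(n) for j in range(n) if i != j]

    @property
    def n_off(self) -> int:
        return self.n_regions * (self.n_regions - 1)

    @property
    def n_params(self) -> int:
        n = self.n_regions
        return self.n_off + n + (n if self.with_input else 0) + 4

    @property
    def slice_off(self) -> slice:
        return slice(0, self.n_off)

    @property
    def slice_self(self) -> slice:
        return slice(self.n_off, self.n_off + self.n_regions)

    @property
    def slice_c(self) -> slice:
        base = self.n_off + self.n_regions
        return slice(base, base + (self.n_regions if self.with_input else 0))

    @property
    def slice_spectral(self) -> slice:
        return slice(self.n_params - 4, self.n_params)

    @property
    def a_indices(self) -> np.ndarray:
        """Indices of all connectivity parameters (off-diagonals + selfs)."""
        return np.arange(self.n_off + self.n_regions)

    def names(self) -> list[str]:
        labels = [f"A[{i},{j}]" for i, j in self.off_diagonal_pairs]
        labels += [f"self[{i}]" for i in range(self.n_regions)]
        if self.with_input:
            labels += [f"C[{i}]" for i in range(self.n_regions)]
        labels += ["neural_log_amp", "neural_exp_dev", "obs_log_amp", "obs_exp_dev"]
        return labels

    def to_vector(self, params: "DcmParameters") -> np.ndarray:
        g = params.graph
        theta = np.empty(self.n_params)
        theta[self.slice_off] = [g.off_diagonal[i, j] for i, j in self.off_diagonal_pairs]
        theta[self.slice_self] = g.self_log_scale
        if self.with_input:
            theta[self.slice_c] = g.driving_weights
        theta[self.slice_spectral] = [
            params.neural_log_amplitude,
            params.neural_exponent_dev,
            params.obs_log_amplitude,
            params.obs_exponent_dev,
        ]
        return theta

    def from_vector(self, theta: np.ndarray) -> "DcmParameters":
        theta = np.asarray(theta, dtype=float).reshape(-1)
        if theta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {theta.size}")
        n = self.n_regions
        off = np.zeros((n, n))
        for k, (i, j) in enumerate(self.off_diagonal_pairs):
            off[i, j] = theta[k]
        weights = theta[self.slice_c] if self.with_input else np.zeros(n)
        graph = ConnectivityGraph(off, theta[self.slice_self], weights)
        sp = theta[self.slice_spectral]
        return DcmParameters(graph, sp[0], sp[1], sp[2], sp[3])


@dataclass(frozen=True)
class DcmParameters:
    """Structured view of one point in DCM parameter space."""

    graph: ConnectivityGraph
    neural_log_amplitude: float = 0.0
    neural_exponent_dev: float = 0.0
    obs_log_amplitude: float = 0.0
    obs_exponent_dev: float = 0.0

    @property
    def neural_amplitude(self) -> float:
        return NEURAL_AMP_BASE * float(np.exp(self.neural_log_amplitude))

    @property
    def neural_exponent(self) -> float:
        return NEURAL_EXP_BASE + self.neural_exponent_dev

    @property
    def obs_amplitude(self) -> float:
        return OBS_AMP_BASE * float(np.exp(self.obs_log_amplitude))

    @property
    def obs_exponent(self) -> float:
        return OBS_EXP_BASE + self.obs_exponent_dev


@dataclass(frozen=True)
class DcmPriors:
    """Gaussian prior over the parameter vector."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(-1)
        cov = sym(np.asarray(self.covariance, dtype=float))
        if cov.shape != (mean.size, mean.size):
            raise ValueError("prior covariance shape inconsistent with mean")
        if np.min(np.linalg.eigvalsh(cov)) <= 0:
            raise ValueError("prior covariance must be positive definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)


def default_priors(layout: DcmParameterLayout, mean: np.ndarray | None = None) -> DcmPriors:
    """Zero-mean shrinkage priors: A ~ N(0, 1/64), self log-scalings
    N(0, 1/256), C N(0, 1/64), spectral parameters N(0, 1/64)."""
    var = np.empty(layout.n_params)
    var[layout.slice_off] = PRIOR_VAR_A
    var[layout.slice_self] = PRIOR_VAR_SELF
    if layout.with_input:
        var[layout.slice_c] = PRIOR_VAR_C
    var[layout.slice_spectral] = PRIOR_VAR_SPECTRAL
    mu = np.zeros(layout.n_params) if mean is None else np.asarray(mean, dtype=float)
    return DcmPriors(mu, np.diag(var))


@dataclass(frozen=True)
class DcmPosterior:
    """Gaussian belief over DCM parameters with free energy bookkeeping."""

    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    accuracy: float
    complexity: float
    n_iterations: int
    converged: bool
    layout: DcmParameterLayout
    priors: DcmPriors
    log_precision: float = 6.0
    scale: float = 1.0
    f_trace: tuple[float, ...] = field(default=())


@dataclass(frozen=True)
class InversionSettings:
    """Knobs of the Gauss-Newton / Levenberg-Marquardt scheme."""

    max_iterations: int = 64
    tolerance_nats: float = 0.01
    n_converged_steps: int = 4
    lm_initial: float = 1.0
    lm_max: float = 1e8
    hyper_prior_mean: float = 6.0
    hyper_prior_variance: float = 1.0 / 128.0


def schedule_power(
    schedule: np.ndarray, tr_s: float, grid: FrequencyGrid, order: int = 8
) -> np.ndarray:
    """One-sided power density of the deterministic input over the run.

    The input spectrum is evaluated through the same autoregressive
    smoothing (default order 8) that produces the data cross-spectra, so
    the input contribution lives in the same feature space as the observed
    spectra; the raw windowed periodogram of a boxcar is spiky across a
    coarse log grid and would not match the smoothed data features.
    """
    from scipy.signal import detrend as _detrend

    u = _detrend(np.asarray(schedule, dtype=float).reshape(-1), type="linear")
    t = u.size
    if not np.any(u) or t <= order + 1:
        return np.zeros(grid.size)
    design = np.column_stack([u[order - 1 - k : t - 1 - k] for k in range(order)])
    target = u[order:]
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    sig2 = float(resid @ resid / target.size)
    f = grid.frequencies
    h = 1.0 / (
        1.0
        - sum(coef[k] * np.exp(-2j * np.pi * f * (k + 1) * tr_s) for k in range(order))
    )
    return 2.0 * tr_s * np.abs(h) ** 2 * sig2


def _spectral_pieces(params: DcmParameters, f: np.ndarray):
    alpha_v = params.neural_amplitude
    beta_v = params.neural_exponent
    alpha_e = params.obs_amplitude
    beta_e = params.obs_exponent
    gv = alpha_v * f ** (-beta_v)
    ge = alpha_e * f ** (-beta_e)
    return gv, ge


def _transfer(params: DcmParameters, f: np.ndarray):
    a_eff = effective_coupling(params.graph)
    n = a_eff.shape[0]
    omega = 2.0 * np.pi * f
    mats = 1j * omega[:, None, None] * np.eye(n)[None] - a_eff[None]
    try:
        m = np.linalg.inv(mats)
    except np.linalg.LinAlgError as exc:
        dets = np.abs(np.linalg.det(mats))
        bad = f[int(np.argmin(dets))]
        raise ValueError(f"singular transfer matrix at frequency {bad:.4g} Hz") from exc
    h = hrf_transfer(f)
    return m, h, h[:, None, None] * m


def predict_csd(
    params: DcmParameters,
    grid: FrequencyGrid,
    schedule_spectrum: np.ndarray | None = None,
) -> CrossSpectrum:
    """Predicted cross-spectral density of the observed BOLD signal."""
    f = grid.frequencies
    n = params.graph.n_regions
    _, _, k = _transfer(params, f)
    gv, ge = _spectral_pieces(params, f)
    gv_mat = gv[:, None, None] * np.eye(n)[None]
    if schedule_spectrum is not None:
        c = params.graph.driving_weights
        gv_mat = gv_mat + np.asarray(schedule_spectrum)[:, None, None] * np.outer(c, c)[None]
    kh = k.conj().transpose(0, 2, 1)
    g = k @ gv_mat @ kh + ge[:, None, None] * np.eye(n)[None]
    g = 0.5 * (g + g.conj().transpose(0, 2, 1))
    idx = np.arange(n)
    g[:, idx, idx] = np.clip(g[:, idx, idx].real, 0.0, None)
    return CrossSpectrum(grid, g)


def csd_to_vector(csd: CrossSpectrum) -> np.ndarray:
    """Stack unique real and imaginary spectrum entries across the grid."""
    n = csd.n_regions
    iu = np.triu_indices(n)
    ius = np.triu_indices(n, k=1)
    real = csd.matrices[:, iu[0], iu[1]].real
    imag = csd.matrices[:, ius[0], ius[1]].imag
    return np.concatenate([real.ravel(), imag.ravel()])


def _matrices_to_vector(mats: np.ndarray) -> np.ndarray:
    n = mats.shape[1]
    iu = np.triu_indices(n)
    ius = np.triu_indices(n, k=1)
    return np.concatenate(
        [mats[:, iu[0], iu[1]].real.ravel(), mats[:, ius[0], ius[1]].imag.ravel()]
    )


def predict_csd_jacobian(
    theta: np.ndarray,
    layout: DcmParameterLayout,
    grid: FrequencyGrid,
    schedule_spectrum: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Prediction vector and its analytic Jacobian at ``theta``.

    Returns (g, J) with g the stacked real/imaginary spectrum vector and J
    of shape (len(g), n_params). Derivatives follow from
    dM = M dA M for M = (2 pi i f I - A_eff)^{-1} and the chain rule through
    the power-law spectra.
    """
    params = layout.from_vector(theta)
    f = grid.frequencies
    n = layout.n_regions
    m, h, k = _transfer(params, f)
    gv, ge = _spectral_pieces(params, f)
    eye = np.eye(n)[None]
    gv_mat = gv[:, None, None] * eye
    u_pow = None
    if schedule_spectrum is not None and layout.with_input:
        c = params.graph.driving_weights
        u_pow = np.asarray(schedule_spectrum, dtype=float)
        gv_mat = gv_mat + u_pow[:, None, None] * np.outer(c, c)[None]
    kh = k.conj().transpose(0, 2, 1)
    kgv = k @ gv_mat
    gvkh = gv_mat @ kh
    g_mats = kgv @ kh + ge[:, None, None] * eye
    g_vec = _matrices_to_vector(g_mats)

    n_data = g_vec.size
    jac = np.empty((n_data, layout.n_params))
    lnf = np.log(f)

    def coupling_column(i: int, j: int, weight: float) -> np.ndarray:
        # dA = weight * e_i e_j^T  ->  dM = M dA M (outer of column i, row j)
        dm = weight * (m[:, :, i][:, :, None] * m[:, j, :][:, None, :])
        dk = h[:, None, None] * dm
        dg = dk @ gvkh + kgv @ dk.conj().transpose(0, 2, 1)
        return _matrices_to_vector(dg)

    col = 0
    for i, j in layout.off_diagonal_pairs:
        jac[:, col] = coupling_column(i, j, 1.0)
        col += 1
    s = params.graph.self_log_scale
    for i in range(n):
        jac[:, col] = coupling_column(i, i, SELF_RATE_HZ * float(np.exp(s[i])))
        col += 1
    if layout.with_input:
        c = params.graph.driving_weights
        for i in range(n):
            dcc = np.zeros((n, n))
            dcc[i, :] += c
            dcc[:, i] += c
            dgv = u_pow[:, None, None] * dcc[None]
            dg = k @ dgv @ kh
            jac[:, col] = _matrices_to_vector(dg)
            col += 1
    # spectral parameters
    base = k @ kh  # K I K^H
    jac[:, col] = _matrices_to_vector(gv[:, None, None] * base)
    jac[:, col + 1] = _matrices_to_vector((gv * -lnf)[:, None, None] * base)
    jac[:, col + 2] = _matrices_to_vector(ge[:, None, None] * eye)
    jac[:, col + 3] = _matrices_to_vector((ge * -lnf)[:, None, None] * eye)
    return g_vec, jac


def free_energy_decomposition(
    posterior: DcmPosterior, priors: DcmPriors | None = None
) -> tuple[float, float]:
    """Split the free energy into accuracy and complexity (nats).

    Complexity is the Gaussian KL divergence of the posterior from the
    prior; accuracy is free energy plus complexity, so the identity
    F = accuracy - complexity holds by construction.
    """
    priors = posterior.priors if priors is None else priors
    complexity = gaussian_kl(
        posterior.mean, posterior.covariance, priors.mean, priors.covariance
    )
    return posterior.free_energy + complexity, complexity


def _free_energy(
    resid: np.ndarray,
    jac: np.ndarray,
    theta: np.ndarray,
    lam: float,
    priors: DcmPriors,
    prior_precision: np.ndarray,
    prior_logdet: float,
    settings: InversionSettings,
    n_data: float | None = None,
) -> tuple[float, np.ndarray]:
    """Variational free energy at (theta, lambda); returns (F, posterior cov)."""
    n_data = resid.size if n_data is None else n_data
    e_lam = np.exp(lam)
    jtj = jac.T @ jac
    precision = e_lam * jtj + prior_precision
    cov = np.linalg.inv(precision)
    cov = sym(cov)
    sse = float(resid @ resid)
    trace_term = float(np.sum(jtj * cov))  # tr(J^T J Sigma)
    diff = theta - priors.mean
    logdet_cov = -logdet_pd(precision, "posterior precision")
    expected_ll = (
        -0.5 * e_lam * (sse + trace_term)
        + 0.5 * n_data * lam
        - 0.5 * n_data * np.log(2.0 * np.pi)
    )
    kl_theta = 0.5 * (
        float(np.sum(prior_precision * cov))
        + diff @ prior_precision @ diff
        - theta.size
        + prior_logdet
        - logdet_cov
    )
    p_lam = 1.0 / settings.hyper_prior_variance
    var_lam = 1.0 / (0.5 * e_lam * (sse + trace_term) + p_lam)
    kl_lam = 0.5 * (
        var_lam * p_lam
        + (lam - settings.hyper_prior_mean) ** 2 * p_lam
        - 1.0
        - np.log(var_lam * p_lam)
    )
    return float(expected_ll - kl_theta - kl_lam), cov


def _update_log_precision(
    resid: np.ndarray,
    jac: np.ndarray,
    cov: np.ndarray,
    lam: float,
    settings: InversionSettings,
    n_data: float | None = None,
) -> float:
    """Newton updates of the residual log-precision hyperparameter."""
    n_data = resid.size if n_data is None else n_data
    sse = float(resid @ resid)
    trace_term = float(np.sum((jac @ cov) * jac))
    p_lam = 1.0 / settings.hyper_prior_variance
    for _ in range(8):
        e_lam = np.exp(lam)
        grad = 0.5 * n_data - 0.5 * e_lam * (sse + trace_term) - p_lam * (
            lam - settings.hyper_prior_mean
        )
        hess = -0.5 * e_lam * (sse + trace_term) - p_lam
        step = np.clip(-grad / hess, -4.0, 4.0)
        lam += step
        if abs(step) < 1e-6:
            break
    return float(lam)


def variational_laplace(
    observed: CrossSpectrum,
    priors: DcmPriors,
    layout: DcmParameterLayout | None = None,
    settings: InversionSettings | None = None,
    schedule_spectrum: np.ndarray | None = None,
) -> DcmPosterior:
    """Fit the spectral DCM to an observed cross-spectrum.

    The data vector is normalized per frequency by the mean observed
    diagonal power at that frequency (the same weights divide the model
    predictions). BOLD cross-spectra span several orders of magnitude
    across the band, so residuals on the raw scale would be dominated by
    the lowest frequencies; the normalization makes the single residual
    log-precision hyperparameter (prior N(6, 1/128)) weight all
    frequencies comparably, on a relative-error scale. Free energy is
    non-decreasing over accepted steps by construction: a Gauss-Newton /
    Levenberg-Marquardt proposal is only accepted when it increases F,
    otherwise the damping doubles.
    """
    settings = settings or InversionSettings()
    if layout is None:
        layout = DcmParameterLayout(observed.n_regions, with_input=schedule_spectrum is not None)
    if layout.n_regions != observed.n_regions:
        raise ValueError(
            f"layout has {layout.n_regions} regions but data has {observed.n_regions}"
        )
    if priors.mean.size != layout.n_params:
        raise ValueError("prior dimension does not match parameter layout")

    n = observed.n_regions
    idx = np.arange(n)
    diag_power = observed.matrices[:, idx, idx].real.mean(axis=1)  # (F,)
    floor = 1e-12 * max(float(diag_power.max()), 1e-300)
    per_freq = np.clip(diag_power, floor, None)
    weights = np.concatenate(
        [np.repeat(per_freq, n * (n + 1) // 2), np.repeat(per_freq, n * (n - 1) // 2)]
    )
    scale = float(per_freq.mean())
    # Effective observation count: a parametric spectral estimate carries at
    # most as many independent numbers as the autoregression behind it, so
    # the likelihood is scaled down accordingly; otherwise the stacked grid
    # values would claim spurious precision and reward overfitting of
    # feature noise.
    n_raw = weights.size
    eff = observed.effective_dof
    n_eff = float(min(n_raw, eff)) if eff is not None else float(n_raw)
    weights = weights / np.sqrt(n_eff / n_raw)
    y = csd_to_vector(observed) / weights

    prior_precision = np.linalg.inv(priors.covariance)
    prior_precision = sym(prior_precision)
    prior_logdet = logdet_pd(priors.covariance, "prior covariance")

    theta = priors.mean.copy()
    if layout.with_input and schedule_spectrum is not None:
        # Input power enters through C C^T, so the free-energy gradient with
        # respect to C vanishes identically at C = 0: a start exactly at the
        # zero prior mean could never recruit the driving input. Break the
        # symmetry with a small positive perturbation of the zero entries.
        c_vals = theta[layout.slice_c]
        theta[layout.slice_c] = np.where(c_vals == 0.0, 0.1, c_vals)
    lam = settings.hyper_prior_mean
    g_vec, jac = predict_csd_jacobian(theta, layout, observed.grid, schedule_spectrum)
    g_vec, jac = g_vec / weights, jac / weights[:, None]
    resid = y - g_vec
    f_cur, cov = _free_energy(
        resid, jac, theta, lam, priors, prior_precision, prior_logdet, settings, n_eff
    )
    if not np.isfinite(f_cur):
        raise FloatingPointError("non-finite free energy at initialization")
    lam = _update_log_precision(resid, jac, cov, lam, settings, n_eff)
    f_cur, cov = _free_energy(
        resid, jac, theta, lam, priors, prior_precision, prior_logdet, settings, n_eff
    )

    lm = settings.lm_initial
    trace = [f_cur]
    small_steps = 0
    converged = False
    iterations = 0
    for iterations in range(1, settings.max_iterations + 1):
        e_lam = np.exp(lam)
        hess = e_lam * (jac.T @ jac) + prior_precision
        grad = e_lam * (jac.T @ resid) - prior_precision @ (theta - priors.mean)
        damped = hess + lm * np.diag(np.diag(hess))
        try:
            step = np.linalg.solve(damped, grad)
        except np.linalg.LinAlgError:
            lm *= 2.0
            continue
        theta_new = theta + step
        g_new, jac_new = predict_csd_jacobian(theta_new, layout, observed.grid, schedule_spectrum)
        g_new, jac_new = g_new / weights, jac_new / weights[:, None]
        resid_new = y - g_new
        f_try, cov_try = _free_energy(
            resid_new, jac_new, theta_new, lam, priors, prior_precision, prior_logdet,
            settings, n_eff
        )
        lam_new = _update_log_precision(resid_new, jac_new, cov_try, lam, settings, n_eff)
        f_new, cov_new = _free_energy(
            resid_new, jac_new, theta_new, lam_new, priors, prior_precision, prior_logdet,
            settings, n_eff
        )
        if np.isfinite(f_new) and f_new > f_cur:
            delta = f_new - f_cur
            theta, lam, resid, jac, cov, f_cur = (
                theta_new,
                lam_new,
                resid_new,
                jac_new,
                cov_new,
                f_new,
            )
            trace.append(f_cur)
            lm = max(lm / 2.0, 1e-8)
            small_steps = small_steps + 1 if delta < settings.tolerance_nats else 0
            if small_steps >= settings.n_converged_steps:
                converged = True
                break
        else:
            lm *= 2.0
            if lm > settings.lm_max:
                converged = True  # no further improvement possible at max damping
                break
    if not np.isfinite(f_cur):
        raise FloatingPointError("non-finite free energy during inversion")
    if not converged:
        logger.warning(
            "variational Laplace did not converge in %d iterations (last dF trace %s)",
            settings.max_iterations,
            trace[-3:],
        )

    complexity = gaussian_kl(theta, cov, priors.mean, priors.covariance)
    free_energy = f_cur
    return DcmPosterior(
        mean=theta,
        covariance=cov,
        free_energy=free_energy,
        accuracy=free_energy + complexity,
        complexity=complexity,
        n_iterations=iterations,
        converged=converged,
        layout=layout,
        priors=priors,
        log_precision=lam,
        scale=scale,
        f_trace=tuple(trace),
    )
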