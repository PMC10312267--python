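"""Group-level inference: empirical-Bayes reestimation and the PEB model.

Two stages follow the per-subject inversions. First, every subject of both
datasets under comparison is re-inverted with the prior mean over the
connectivity parameters set to the grand average of all subjects' posterior
means (across both datasets); this can rescue subjects whose first fit fell
into a different local optimum. Second, each dataset's subject posteriors
are summarized by a hierarchical parametric-empirical-Bayes (PEB) model

    level 2:  theta_s = X beta + eps_s,   eps_s ~ N(0, Gamma)
    level 1:  subject evidence, represented by the Gaussian posterior

whose design matrix ``X`` carries an all-ones group-mean column (plus any
between-subject covariates), yielding a Gaussian belief over the group
parameters ``beta`` and a free energy for the whole hierarchy.

The PEB consumes first-level Gaussian posteriors directly, never raw
timeseries: each subject contributes the likelihood ratio between its
posterior and its own prior (the Bayesian-model-reduction representation of
the subject evidence), so replacing the first-level prior by the group
model is exact for linear-Gaussian beliefs. The between-subject covariance
is ``exp(-gamma)`` times one sixteenth of the within-subject prior
covariance, with the single log-precision hyperparameter ``gamma``
(hyperprior N(0, 1/16)) optimized by maximizing the group free energy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ._gaussian import logdet_pd, nearest_psd, sym
from .model import (
    DcmParameterLayout,
    DcmPosterior,
    DcmPriors,
    InversionSettings,
    variational_laplace,
)
from .spectra import CrossSpectrum

__all__ = [
    "PebModel",
    "SubjectData",
    "fit_peb",
    "reestimate_with_group_priors",
    "marginal_belief",
    "BETWEEN_VARIANCE_FRACTION",
    "GAMMA_PRIOR_VARIANCE",
]

#: Expected between-subject variance as a fraction of the within-subject
#: prior variance (at gamma = 0).
BETWEEN_VARIANCE_FRACTION = 1.0 / 16.0

#: Hyperprior variance of the between-subject log precision gamma. Tight
#: (the conventional empirical-Bayes default): the expected between-subject
#: covariance acts as a floor, so the group-level precision is not driven
#: by per-subject estimation scatter.
GAMMA_PRIOR_VARIANCE = 1.0 / 16.0

_GAMMA_BOUNDS = (-16.0, 16.0)


@dataclass(frozen=True)
class SubjectData:
    """Handle pairing a subject's observed spectrum with its input power."""

    spectrum: CrossSpectrum
    schedule_spectrum: np.ndarray | None = None


@dataclass(frozen=True)
class PebModel:
    """Hierarchical group model fitted to one dataset's subject posteriors."""

    design_matrix: np.ndarray  # (n_subjects, n_covariates), first column ones
    beta_mean: np.ndarray  # (n_covariates * n_params,)
    beta_covariance: np.ndarray
    between_subject_covariance: np.ndarray
    free_energy: float
    prior_mean: np.ndarray
    prior_covariance: np.ndarray
    gamma: float
    param_names: tuple[str, ...]
    n_regions: int
    connection_index: dict  # (i, j) -> index of A[i, j] within a covariate block

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_covariates(self) -> int:
        return self.design_matrix.shape[1]


def marginal_belief(
    mean: np.ndarray, cov: np.ndarray, indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal of a Gaussian belief over a subset of coordinates."""
    indices = np.asarray(indices, dtype=int)
    return mean[indices], cov[np.ix_(indices, indices)]


def _shared_a_indices(posteriors: list[DcmPosterior]) -> np.ndarray:
    layouts = {(p.layout.n_regions,) for p in posteriors}
    if len(layouts) != 1:
        raise ValueError("posteriors have mismatched parameter orders (region counts differ)")
    return posteriors[0].layout.a_indices


def reestimate_with_group_priors(
    posteriors: list[DcmPosterior],
    data: list[SubjectData],
    prior_covariance: np.ndarray | None = None,
    settings: InversionSettings | None = None,
) -> list[DcmPosterior]:
    """Re-invert every subject under grand-average connectivity priors.

    The prior mean over the connectivity parameters (between-region rates
    and self log-scalings) is replaced by the average posterior mean over
    all supplied subjects — from both datasets when comparing two — while
    the remaining parameters keep their default prior means. The prior
    covariance defaults to each subject's original prior covariance.
    """
    if len(posteriors) == 0:
        raise ValueError("no posteriors supplied")
    if len(posteriors) != len(data):
        raise ValueError("one data handle per posterior required")
    a_idx = _shared_a_indices(posteriors)
    grand = np.mean([p.mean[a_idx] for p in posteriors], axis=0)
    out = []
    for post, handle in zip(posteriors, data):
        mean = post.priors.mean.copy()
        mean[a_idx] = grand
        cov = post.priors.covariance if prior_covariance is None else prior_covariance
        priors = DcmPriors(mean, cov)
        out.append(
            variational_laplace(
                handle.spectrum,
                priors,
                layout=post.layout,
                settings=settings,
                schedule_spectrum=handle.schedule_spectrum,
            )
        )
    return out


def _subject_likelihood_terms(
    post: DcmPosterior, indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """BMR representation of a subject's evidence over the chosen subset.

    Returns (Lambda, h, c): the data precision Lambda = Sigma^-1 - Sigma0^-1
    (clipped to the PSD cone), the information vector h = Sigma^-1 mu -
    Sigma0^-1 mu0 and the gamma-independent log constant of the likelihood
    ratio N(theta; mu, Sigma) / N(theta; mu0, Sigma0).
    """
    mu, cov = marginal_belief(post.mean, post.covariance, indices)
    mu0, cov0 = marginal_belief(post.priors.mean, post.priors.covariance, indices)
    prec = np.linalg.inv(nearest_psd(cov, floor=1e-12))
    prec0 = np.linalg.inv(cov0)
    lam = nearest_psd(sym(prec - prec0))
    h = prec @ mu - prec0 @ mu0
    const = 0.5 * (
        logdet_pd(cov0, "subject prior covariance")
        - logdet_pd(nearest_psd(cov, floor=1e-12), "subject posterior covariance")
        - mu @ prec @ mu
        + mu0 @ prec0 @ mu0
    )
    return lam, h, const


def fit_peb(
    posteriors: list[DcmPosterior],
    design_matrix: np.ndarray | None = None,
    indices: np.ndarray | None = None,
    gamma_fixed: float | None = None,
    gamma_prior_variance: float = GAMMA_PRIOR_VARIANCE,
) -> PebModel:
    """Fit the hierarchical PEB model to one dataset's subject posteriors.

    By default the group model covers the connectivity parameters (the
    between-region rates and self log-scalings, the block shared by rest
    and task fits) with an intercept-only design matrix. ``gamma_fixed``
    pins the between-subject log precision instead of optimizing it.
    """
    if len(posteriors) < 2:
        raise ValueError("PEB requires >= 2 subjects")
    n_sub = len(posteriors)
    if indices is None:
        indices = _shared_a_indices(posteriors)
    indices = np.asarray(indices, dtype=int)
    p = indices.size

    if design_matrix is None:
        x = np.ones((n_sub, 1))
    else:
        x = np.atleast_2d(np.asarray(design_matrix, dtype=float))
        if x.shape[0] != n_sub:
            raise ValueError(f"design matrix has {x.shape[0]} rows for {n_sub} subjects")
        if not np.allclose(x[:, 0], 1.0):
            raise ValueError("first design-matrix column must be all ones (group mean)")
        if n_sub < x.shape[1]:
            raise ValueError("fewer subjects than covariates")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("singular design matrix")
    n_cov = x.shape[1]

    # group-level priors: within-subject priors for the mean column,
    # zero-mean shrinkage of the same width for other covariates
    mu0_w, cov0_w = marginal_belief(
        posteriors[0].priors.mean, posteriors[0].priors.covariance, indices
    )
    prior_mean = np.concatenate([mu0_w] + [np.zeros(p)] * (n_cov - 1))
    prior_cov = np.kron(np.eye(n_cov), cov0_w)
    prior_prec = np.linalg.inv(prior_cov)

    terms = [_subject_likelihood_terms(post, indices) for post in posteriors]
    d_between = BETWEEN_VARIANCE_FRACTION * cov0_w  # Gamma at gamma = 0

    def _assemble(gamma: float):
        gamma_inv_scale = float(np.exp(gamma))
        gam = d_between / gamma_inv_scale
        gam_prec = np.linalg.inv(gam)
        logdet_gam = logdet_pd(gam, "between-subject covariance")
        q_mat = np.zeros((n_cov * p, n_cov * p))
        u_vec = np.zeros(n_cov * p)
        const = 0.0
        for (lam, h, c), x_s in zip(terms, x):
            p_s = lam + gam_prec
            p_s_inv = np.linalg.inv(p_s)
            m_s = sym(gam_prec - gam_prec @ p_s_inv @ gam_prec)
            w_s = gam_prec @ p_s_inv @ h
            q_mat += np.kron(np.outer(x_s, x_s), m_s)
            u_vec += np.kron(x_s, w_s)
            const += (
                c
                - 0.5 * (logdet_gam + logdet_pd(p_s, "subject marginal precision"))
                + 0.5 * h @ p_s_inv @ h
            )
        post_prec = sym(q_mat + prior_prec)
        post_cov = np.linalg.inv(post_prec)
        info = u_vec + prior_prec @ prior_mean
        beta = post_cov @ info
        log_z = (
            const
            - 0.5 * (logdet_pd(prior_cov, "group prior") - logdet_pd(post_cov, "group posterior"))
            + 0.5 * (info @ post_cov @ info - prior_mean @ prior_prec @ prior_mean)
        )
        log_z += -0.5 * gamma**2 / gamma_prior_variance - 0.5 * np.log(
            2.0 * np.pi * gamma_prior_variance
        )
        return log_z, beta, sym(post_cov), gam

    if gamma_fixed is not None:
        gamma = float(gamma_fixed)
    else:
        res = minimize_scalar(
            lambda g: -_assemble(g)[0],
            bounds=_GAMMA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-4},
        )
        gamma = float(res.x)

    log_z, beta, beta_cov, gam = _assemble(gamma)
    # Laplace correction for the optimized hyperparameter
    eps = 1e-2
    if gamma_fixed is None and _GAMMA_BOUNDS[0] + eps < gamma < _GAMMA_BOUNDS[1] - eps:
        g_plus = _assemble(gamma + eps)[0]
        g_minus = _assemble(gamma - eps)[0]
        curvature = (g_plus - 2.0 * log_z + g_minus) / eps**2
        if curvature < 0:
            log_z += 0.5 * np.log(2.0 * np.pi / -curvature)
    free_energy = float(log_z + sum(p_.free_energy for p_ in posteriors))

    layout = posteriors[0].layout
    base_names = np.asarray(layout.names())[indices]
    names = tuple(
        f"cov{k}:{nm}" if k else nm for k in range(n_cov) for nm in base_names
    )
    conn_index = {
        pair: col for col, pair in enumerate(layout.off_diagonal_pairs)
    }
    return PebModel(
        design_matrix=x,
        beta_mean=beta,
        beta_covariance=beta_cov,
        between_subject_covariance=gam,
        free_energy=free_energy,
        prior_mean=prior_mean,
        prior_covariance=prior_cov,
        gamma=gamma,
        param_names=names,
        n_regions=layout.n_regions,
        connection_index=conn_index,
    )
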