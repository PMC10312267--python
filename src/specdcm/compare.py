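"""Bayesian data comparison: scoring datasets by what they taught the model.

Datasets fitted with the same model cannot be compared by Bayes factors —
the data differ — so they are compared by how much each one informs the
group-level connectivity belief:

* parameter certainty  S = -0.5 ln |2 pi e Sigma|, the negative entropy of
  the group posterior covariance, in nats;
* information gain over parameters, the Gaussian KL divergence from the
  group prior to the group posterior, in nats;
* information gain over models, the discrete KL divergence from a uniform
  prior over candidate network structures to the posterior over those
  structures, with per-model evidence obtained analytically by Bayesian
  model reduction (BMR) of the group belief.

Differences between datasets are reported relative to the worst performer
and labelled on the conventional nats scale: below 1.1 insufficient,
1.1-3 positive, 3-5 strong, beyond 5 very strong evidence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ._gaussian import gaussian_kl, logdet_pd, sym
from .group import PebModel

__all__ = [
    "ModelSpace",
    "QualityIndices",
    "QualityReport",
    "parameter_certainty",
    "information_gain_parameters",
    "build_model_space",
    "bayesian_model_reduction",
    "information_gain_models",
    "label_evidence",
    "compare_datasets",
    "SWITCHED_OFF_VARIANCE",
]

#: Prior variance encoding a switched-off connection (near-zero, kept
#: finite for numerical stability).
SWITCHED_OFF_VARIANCE = 1e-6

_EVIDENCE_BINS = ((1.1, "insufficient"), (3.0, "positive"), (5.0, "strong"))


@dataclass(frozen=True)
class ModelSpace:
    """Candidate network structures as binary masks over the A matrix.

    ``masks[m][i, j] == 0`` switches the connection j -> i off in model m
    (its prior collapses to mean zero, variance SWITCHED_OFF_VARIANCE).
    Self-connections are always retained and the full model is included.
    Prior model probabilities are uniform.
    """

    masks: tuple[np.ndarray, ...]
    prior_model_probabilities: np.ndarray

    def __post_init__(self) -> None:
        masks = tuple(np.asarray(m, dtype=int) for m in self.masks)
        if not masks:
            raise ValueError("empty model space")
        n = masks[0].shape[0]
        seen = set()
        full_present = False
        for m in masks:
            if m.shape != (n, n):
                raise ValueError("masks must share the region count")
            if np.any(np.diag(m) == 0):
                raise ValueError("masks must retain all self-connections")
            key = m.tobytes()
            if key in seen:
                raise ValueError("duplicate masks in model space")
            seen.add(key)
            full_present = full_present or bool(np.all(m == 1))
        if not full_present:
            raise ValueError("model space must include the full model")
        probs = np.asarray(self.prior_model_probabilities, dtype=float)
        if probs.shape != (len(masks),) or not np.allclose(probs, 1.0 / len(masks)):
            raise ValueError("prior model probabilities must be uniform and sum to 1")
        object.__setattr__(self, "masks", masks)
        object.__setattr__(self, "prior_model_probabilities", probs)

    @property
    def n_models(self) -> int:
        return len(self.masks)


@dataclass(frozen=True)
class QualityIndices:
    """The three data-quality statistics for one dataset, in nats."""

    parameter_certainty: float
    info_gain_parameters: float
    info_gain_models: float
    dataset_label: str


@dataclass(frozen=True)
class QualityReport:
    """Pairwise comparison of two datasets' quality indices."""

    indices: tuple[QualityIndices, QualityIndices]
    differences: dict  # index name -> best-minus-worst difference (>= 0)
    best: dict  # index name -> label of the better dataset
    evidence_labels: dict  # index name -> evidence category

    def to_dict(self) -> dict:
        return {
            "indices": [
                {
                    "dataset": ix.dataset_label,
                    "parameter_certainty": ix.parameter_certainty,
                    "info_gain_parameters": ix.info_gain_parameters,
                    "info_gain_models": ix.info_gain_models,
                }
                for ix in self.indices
            ],
            "differences": dict(self.differences),
            "best": dict(self.best),
            "evidence_labels": dict(self.evidence_labels),
        }


def parameter_certainty(covariance: np.ndarray) -> float:
    """Negative entropy -0.5 ln |2 pi e Sigma| of a Gaussian belief, nats."""
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    k = cov.shape[0]
    w = np.linalg.eigvalsh(sym(cov))
    if w.min() <= 0:
        raise ValueError(
            f"covariance not positive definite (smallest eigenvalue {w.min():.3e})"
        )
    logdet = logdet_pd(cov, "covariance")
    return float(-0.5 * (k * np.log(2.0 * np.pi * np.e) + logdet))


def information_gain_parameters(
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    posterior_mean: np.ndarray,
    posterior_cov: np.ndarray,
) -> float:
    """Gaussian KL divergence KL(posterior || prior), in nats."""
    return gaussian_kl(posterior_mean, posterior_cov, prior_mean, prior_cov)


def build_model_space(
    n_regions: int,
    scheme: str = "leave-one-out",
    custom_masks: list[np.ndarray] | None = None,
) -> ModelSpace:
    """Construct the candidate structures compared by model-space gain.

    ``leave-one-out`` pairs the full model with one reduced model per
    between-region connection in which only that connection is switched
    off — 21 models for five regions. ``custom`` validates user masks.
    """
    if n_regions < 2:
        raise ValueError("need >= 2 regions")
    if scheme == "leave-one-out":
        full = np.ones((n_regions, n_regions), dtype=int)
        masks = [full]
        for i in range(n_regions):
            for j in range(n_regions):
                if i == j:
                    continue
                m = full.copy()
                m[i, j] = 0
                masks.append(m)
    elif scheme == "custom":
        if not custom_masks:
            raise ValueError("custom scheme requires custom_masks")
        masks = list(custom_masks)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    n_models = len(masks)
    return ModelSpace(tuple(masks), np.full(n_models, 1.0 / n_models))


def bayesian_model_reduction(
    posterior_mean: np.ndarray,
    posterior_cov: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    reduced_prior_mean: np.ndarray,
    reduced_prior_cov: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Analytic posterior and evidence change under a reduced prior.

    For linear-Gaussian beliefs the evidence of the model with the reduced
    prior follows in closed form from the full model's prior and posterior.
    Returns (reduced mean, reduced covariance, delta_evidence in nats).
    """
    mu = np.asarray(posterior_mean, dtype=float).reshape(-1)
    mu0 = np.asarray(prior_mean, dtype=float).reshape(-1)
    mur = np.asarray(reduced_prior_mean, dtype=float).reshape(-1)
    if not (mu.shape == mu0.shape == mur.shape):
        raise ValueError("dimension mismatch across beliefs")
    pi = np.linalg.inv(sym(np.atleast_2d(posterior_cov)))
    pi0 = np.linalg.inv(sym(np.atleast_2d(prior_cov)))
    pir = np.linalg.inv(sym(np.atleast_2d(reduced_prior_cov)))
    pi_red = sym(pi - pi0 + pir)
    w = np.linalg.eigvalsh(pi_red)
    if w.min() <= 0:
        raise ValueError(
            "reduced posterior precision not positive definite "
            f"(smallest eigenvalue {w.min():.3e}); priors too incompatible"
        )
    info = pi @ mu - pi0 @ mu0 + pir @ mur
    cov_red = np.linalg.inv(pi_red)
    mu_red = cov_red @ info
    delta = 0.5 * (
        logdet_pd(np.atleast_2d(posterior_cov), "posterior")  # ln det Pi ... via -logdet cov
        * -1.0
        + logdet_pd(np.atleast_2d(reduced_prior_cov), "reduced prior") * -1.0
        - logdet_pd(np.atleast_2d(prior_cov), "prior") * -1.0
        - logdet_pd(cov_red, "reduced posterior") * -1.0
    ) + 0.5 * (info @ cov_red @ info - mu @ pi @ mu + mu0 @ pi0 @ mu0 - mur @ pir @ mur)
    return mu_red, sym(cov_red), float(delta)


def _mask_to_reduced_prior(
    peb: PebModel, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reduced group prior implied by a structure mask.

    Switched-off between-region connections get mean zero and variance
    SWITCHED_OFF_VARIANCE in every covariate block.
    """
    p = peb.n_params // peb.n_covariates
    mean = peb.prior_mean.copy()
    cov = peb.prior_covariance.copy()
    off_positions = [
        peb.connection_index[pair]
        for pair in peb.connection_index
        if mask[pair] == 0
    ]
    for k in range(peb.n_covariates):
        for pos in off_positions:
            idx = k * p + pos
            mean[idx] = 0.0
            cov[idx, :] = 0.0
            cov[:, idx] = 0.0
            cov[idx, idx] = SWITCHED_OFF_VARIANCE
    return mean, cov


def information_gain_models(peb: PebModel, space: ModelSpace) -> float:
    """Discrete KL from the uniform structure prior to its posterior, nats.

    Model log evidences are obtained by BMR of the PEB belief; posterior
    model probabilities follow by log-sum-exp-normalized exponentiation.
    The result lies in [0, ln M] for M models.
    """
    log_ev = np.empty(space.n_models)
    for m, mask in enumerate(space.masks):
        mean_r, cov_r = _mask_to_reduced_prior(peb, mask)
        _, _, delta = bayesian_model_reduction(
            peb.beta_mean,
            peb.beta_covariance,
            peb.prior_mean,
            peb.prior_covariance,
            mean_r,
            cov_r,
        )
        log_ev[m] = delta
    log_post = log_ev - logsumexp(log_ev)
    probs = np.exp(log_post)
    kl = float(np.sum(probs * (log_post + np.log(space.n_models))))
    return float(min(max(kl, 0.0), np.log(space.n_models)))


def label_evidence(delta_nats: float) -> str:
    """Evidence category for a nonnegative nats difference."""
    if delta_nats < 0:
        raise ValueError("evidence difference must be >= 0")
    for upper, label in _EVIDENCE_BINS:
        if delta_nats < upper:
            return label
    return "very strong"


def dataset_indices(peb: PebModel, space: ModelSpace, label: str) -> QualityIndices:
    """All three quality indices of one dataset from its group belief."""
    return QualityIndices(
        parameter_certainty=parameter_certainty(peb.beta_covariance),
        info_gain_parameters=information_gain_parameters(
            peb.prior_mean, peb.prior_covariance, peb.beta_mean, peb.beta_covariance
        ),
        info_gain_models=information_gain_models(peb, space),
        dataset_label=label,
    )


def compare_datasets(
    peb_a: PebModel,
    peb_b: PebModel,
    space: ModelSpace | None = None,
    label_a: str = "dataset_a",
    label_b: str = "dataset_b",
) -> QualityReport:
    """Score two fitted datasets and report differences best-minus-worst.

    Both datasets must have been fitted against the same model structure
    (same regions, parameterization and priors). Certainty and parameter
    gain are computed from the same group belief used for the model-space
    gain.
    """
    if peb_a.n_params != peb_b.n_params or peb_a.n_regions != peb_b.n_regions:
        raise ValueError("datasets were fitted with mismatched parameterizations")
    if not np.allclose(peb_a.prior_covariance, peb_b.prior_covariance):
        raise ValueError("datasets must share group priors for a fair comparison")
    if space is None:
        space = build_model_space(peb_a.n_regions)
    ix_a = dataset_indices(peb_a, space, label_a)
    ix_b = dataset_indices(peb_b, space, label_b)
    differences, best, labels = {}, {}, {}
    for name in ("parameter_certainty", "info_gain_parameters", "info_gain_models"):
        va, vb = getattr(ix_a, name), getattr(ix_b, name)
        delta = abs(va - vb)
        differences[name] = delta
        best[name] = label_a if va >= vb else label_b
        labels[name] = label_evidence(delta)
    return QualityReport((ix_a, ix_b), differences, best, labels)
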