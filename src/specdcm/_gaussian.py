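"""Multivariate-Gaussian linear algebra helpers shared across the package.

All routines operate on plain numpy arrays and raise :class:`ValueError`
with a diagnostic message on non-positive-definite input, so callers can
surface the offending quantity (smallest eigenvalue, conditioning).
"""
from __future__ import annotations

import numpy as np
from scipy import linalg as sla

__all__ = [
    "sym",
    "logdet_pd",
    "solve_pd",
    "gaussian_kl",
    "nearest_psd",
]


def sym(a: np.ndarray) -> np.ndarray:
    """Symmetrize a square matrix (average with its transpose)."""
    return 0.5 * (a + a.T)


def _cholesky(a: np.ndarray, name: str) -> np.ndarray:
    try:
        return sla.cholesky(sym(np.asarray(a, dtype=float)), lower=True)
    except sla.LinAlgError as exc:
        w = np.linalg.eigvalsh(sym(np.asarray(a, dtype=float)))
        raise ValueError(
            f"{name} is not positive definite (smallest eigenvalue {w.min():.3e})"
        ) from exc


def logdet_pd(a: np.ndarray, name: str = "matrix") -> float:
    """Log-determinant of a symmetric positive-definite matrix via Cholesky."""
    chol = _cholesky(a, name)
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def solve_pd(a: np.ndarray, b: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Solve ``a x = b`` for symmetric positive-definite ``a``."""
    chol = _cholesky(a, name)
    return sla.cho_solve((chol, True), np.asarray(b, dtype=float))


def gaussian_kl(
    mean_q: np.ndarray,
    cov_q: np.ndarray,
    mean_p: np.ndarray,
    cov_p: np.ndarray,
) -> float:
    """KL divergence KL(q || p) between multivariate Gaussians, in nats.

    Closed form for q = N(mean_q, cov_q) and p = N(mean_p, cov_p):

        KL = 0.5 [ tr(cov_p^-1 cov_q) + d' cov_p^-1 d - k + ln |cov_p|/|cov_q| ]

    with d = mean_p - mean_q and k the dimension.
    """
    mean_q = np.atleast_1d(np.asarray(mean_q, dtype=float))
    mean_p = np.atleast_1d(np.asarray(mean_p, dtype=float))
    cov_q = np.atleast_2d(np.asarray(cov_q, dtype=float))
    cov_p = np.atleast_2d(np.asarray(cov_p, dtype=float))
    if mean_q.shape != mean_p.shape or cov_q.shape != cov_p.shape:
        raise ValueError(
            f"dimension mismatch: q has {mean_q.shape}/{cov_q.shape}, "
            f"p has {mean_p.shape}/{cov_p.shape}"
        )
    k = mean_q.size
    chol_p = _cholesky(cov_p, "cov_p")
    logdet_p = 2.0 * float(np.sum(np.log(np.diag(chol_p))))
    logdet_q = logdet_pd(cov_q, "cov_q")
    diff = mean_p - mean_q
    sol_cov = sla.cho_solve((chol_p, True), cov_q)
    sol_diff = sla.cho_solve((chol_p, True), diff)
    kl = 0.5 * (np.trace(sol_cov) + diff @ sol_diff - k + logdet_p - logdet_q)
    # guard against tiny negative round-off for (near-)identical beliefs
    return float(max(kl, 0.0)) if kl > -1e-9 else float(kl)


def nearest_psd(a: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    w, v = np.linalg.eigh(sym(a))
    w = np.clip(w, floor, None)
    return sym((v * w) @ v.T)
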