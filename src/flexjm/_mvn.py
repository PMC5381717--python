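"""Multivariate normal orthant/CDF probabilities.

Genz separation-of-variables quadrature over a fixed scrambled Sobol
point set.  Because the point set is frozen (one internal seed), the
returned value is a smooth deterministic function of the upper limits
and the covariance matrix, which keeps finite-difference gradients of
the likelihood well behaved.  All accumulation is in the log domain so
probabilities far in the tail do not underflow.

Batched variants evaluate many problems of a common dimension at once;
this is the hot path of the joint-model likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtri_exp, logsumexp
from scipy.stats import qmc

__all__ = ["mvn_cdf", "mvn_logcdf", "mvn_logcdf_batch"]

_SOBOL_SEED = 123456789
_POINT_CACHE: dict = {}

# beyond this the conditioning variable's contribution is numerically exact
_Y_CLIP = 8.2


def _points(dim: int, n_points: int) -> np.ndarray:
    """Fixed scrambled-Sobol points in (0,1)^dim, cached."""
    key = (dim, n_points)
    if key not in _POINT_CACHE:
        eng = qmc.Sobol(d=dim, scramble=True, seed=_SOBOL_SEED)
        w = eng.random(n_points)
        # keep strictly inside (0,1)
        eps = np.finfo(float).tiny
        _POINT_CACHE[key] = np.clip(w, eps, 1 - 1e-16)
    return _POINT_CACHE[key]


def _chol_psd(cov: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Batched Cholesky with a small diagonal jitter escalation."""
    cov = np.asarray(cov, dtype=float)
    scale = np.maximum(np.einsum("...ii->...", cov).real / cov.shape[-1], 1.0)
    for k in range(6):
        try:
            bump = 0.0 if k == 0 else jitter * (10.0**k)
            eye = np.eye(cov.shape[-1])
            return np.linalg.cholesky(cov + bump * scale[..., None, None] * eye)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix is not positive semidefinite")


def mvn_logcdf_batch(upper: np.ndarray, cov: np.ndarray, n_points: int = 512) -> np.ndarray:
    """log P(Z <= upper) for a batch of problems of common dimension K.

    Parameters
    ----------
    upper : (..., K) upper limits (lower limits are -inf).
    cov : (..., K, K) covariance matrices.
    n_points : size of the fixed Sobol point set (power of two).
    """
    upper = np.asarray(upper, dtype=float)
    cov = np.asarray(cov, dtype=float)
    K = upper.shape[-1]
    if K == 0:
        return np.zeros(upper.shape[:-1])
    L = _chol_psd(cov)
    if K == 1:
        return log_ndtr(upper[..., 0] / L[..., 0, 0])

    w = _points(K - 1, n_points)  # (P, K-1)
    batch_shape = upper.shape[:-1]
    P = n_points
    log_e_prev = log_ndtr(upper[..., 0] / L[..., 0, 0])  # (...,)
    log_f = np.broadcast_to(log_e_prev[..., None], batch_shape + (P,)).copy()
    y = np.empty(batch_shape + (P, K - 1))
    log_w = np.log(w)
    for i in range(1, K):
        # y_{i-1} = Phi^{-1}(w * e_{i-1}) computed in the log domain
        z = log_w[:, i - 1] + (log_e_prev[..., None] if i == 1 else log_e_prev)
        y[..., :, i - 1] = np.clip(ndtri_exp(np.minimum(z, -1e-300)), -_Y_CLIP, _Y_CLIP)
        num = upper[..., i, None] - np.einsum(
            "...j,...pj->...p", L[..., i, :i], y[..., :, :i]
        )
        log_e_prev = log_ndtr(num / L[..., i, i, None])  # (..., P)
        log_f = log_f + log_e_prev
    return logsumexp(log_f, axis=-1) - np.log(P)


def mvn_logcdf(upper, cov, n_points: int = 8192) -> float:
    """log P(Z <= upper) for one problem, at reporting accuracy."""
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if upper.size == 0:
        return 0.0
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise np.linalg.LinAlgError("covariance matrix is not symmetric")
    return float(mvn_logcdf_batch(upper[None, :], cov[None, :, :], n_points=n_points)[0])


def mvn_cdf(upper, cov, n_points: int = 8192) -> float:
    """P(Z <= upper) for Z ~ N(0, cov); the empty problem returns 1.

    Deterministic for a fixed ``n_points`` (the internal point set is
    frozen), reproducible to well beyond six digits.
    """
    return float(np.exp(mvn_logcdf(upper, cov, n_points=n_points)))
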