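"""Dynamic prediction of conditional survival probabilities.

Conditioning a subject's random spline coefficients on their
longitudinal history through the end of interval ``r`` *and* on survival
of intervals ``1..r`` yields a multivariate skew-normal law: a Gaussian
density times a product of probit factors.  Sampling is MCMC-free via
the latent representation ``u = D b + c - eps`` with ``u`` restricted to
the nonnegative orthant: draw the truncated latent Gaussian, then the
Gaussian conditional of ``b`` given ``u``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

from ._mvn import mvn_logcdf
from .data import ModelParams, SubjectRecord
from .likelihood import _assoc_rows, gaussian_conjugacy
from .timegrid import TimePartition

__all__ = [
    "SkewNormalPosterior",
    "PredictionResult",
    "posterior_b",
    "sample_posterior",
    "predict_survival",
]

# below this orthant probability the rejection sampler gives way to a Gibbs
# sweep inside the orthant (documented approximate fallback)
REJECTION_MIN_ACCEPT = 1e-3
GIBBS_BURNIN = 50
UNDERFLOW_LOG_NORMALIZER = np.log(1e-12)


@dataclass
class SkewNormalPosterior:
    """Law of ``b`` proportional to ``N(b; mu, Omega) * Phi_K(D b + c)``."""

    mu: np.ndarray  # (d,)
    Omega: np.ndarray  # (d, d)
    D: np.ndarray  # (K, d)
    c: np.ndarray  # (K,)

    @property
    def K(self) -> int:
        return int(self.D.shape[0])

    def log_normalizer(self) -> float:
        """log Phi_K(D mu + c; 0, I + D Omega D')."""
        if self.K == 0:
            return 0.0
        m = self.D @ self.mu + self.c
        S = np.eye(self.K) + self.D @ self.Omega @ self.D.T
        return mvn_logcdf(m, S)

    def logpdf(self, b: np.ndarray) -> np.ndarray:
        """Normalized log density (vectorized over rows of ``b``)."""
        b = np.atleast_2d(b)
        L = np.linalg.cholesky(self.Omega)
        r = np.linalg.solve(L, (b - self.mu).T).T
        lg = -0.5 * (
            b.shape[1] * np.log(2 * np.pi)
            + 2 * np.sum(np.log(np.diag(L)))
            + np.sum(r * r, axis=1)
        )
        if self.K:
            lg = lg + np.sum(log_ndtr(b @ self.D.T + self.c), axis=1)
        return lg - self.log_normalizer()


@dataclass
class PredictionResult:
    pi: float
    samples_b: np.ndarray  # (L, d)
    b_hat: np.ndarray
    r: int
    s: int
    seed: Optional[int]
    summary: str = "median"


def posterior_b(
    params: ModelParams,
    subject: SubjectRecord,
    r: int,
    part: TimePartition,
    parameterization: str = "intercept_slope",
) -> SkewNormalPosterior:
    """Posterior of ``b`` given measurements up to ``t(r) = k_r`` and
    survival of intervals ``1..r``.

    The conditioning event is ``S > r``, so all ``r`` probit constraints
    carry a positive sign.
    """
    if not 1 <= r < part.M:
        raise ValueError(f"prediction interval r={r} must satisfy 1 <= r < M={part.M}")
    if subject.x_surv is None or subject.x_surv.shape[0] < r:
        raise ValueError(f"subject {subject.id}: survival covariates missing")
    hist = subject.truncated(float(part.boundaries[r]))
    conj = gaussian_conjugacy(hist, params, part)
    d = params.beta.size
    D = np.empty((r, d))
    c = np.empty(r)
    for k in range(1, r + 1):
        A = _assoc_rows(k, part, parameterization, d)
        load = params.gamma_for_interval(k) @ A
        D[k - 1] = load
        c[k - 1] = subject.x_surv[k - 1] @ params.alpha_tilde + load @ params.beta
    return SkewNormalPosterior(mu=conj.mu_post, Omega=conj.Sigma_post, D=D, c=c)


def _gibbs_orthant(m, S, n_draws, rng, burnin=GIBBS_BURNIN):
    """Gibbs sampler for N(m, S) restricted to the nonnegative orthant."""
    K = m.size
    prec = np.linalg.inv(S)
    cond_sd = 1.0 / np.sqrt(np.diag(prec))
    u = np.maximum(m, 0.1)
    out = np.empty((n_draws, K))
    tiny = np.finfo(float).tiny
    for it in range(burnin + n_draws):
        for k in range(K):
            # conditional mean of u_k given the rest
            mk = m[k] - (prec[k] @ (u - m) - prec[k, k] * (u[k] - m[k])) / prec[k, k]
            lo = ndtr((0.0 - mk) / cond_sd[k])
            w = rng.uniform(lo + tiny, 1.0 - 1e-16)
            u[k] = mk + cond_sd[k] * ndtri(w)
        if it >= burnin:
            out[it - burnin] = u
    return out


def sample_posterior(
    post: SkewNormalPosterior, L: int, seed: Optional[int] = None
) -> np.ndarray:
    """Draw ``L`` exact samples of ``b`` from the skew-normal posterior.

    Exact rejection from the untruncated latent Gaussian when the
    acceptance rate permits; otherwise a Gibbs sweep inside the orthant
    (approximate fallback for deep-tail histories).
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    rng = np.random.default_rng(seed)
    d = post.mu.size
    Lo = np.linalg.cholesky(post.Omega + 1e-12 * np.eye(d) * max(np.trace(post.Omega) / d, 1.0))
    if post.K == 0:
        return post.mu + rng.standard_normal((L, d)) @ Lo.T

    m_u = post.D @ post.mu + post.c
    S_u = np.eye(post.K) + post.D @ post.Omega @ post.D.T
    log_norm = mvn_logcdf(m_u, S_u)
    if log_norm < UNDERFLOW_LOG_NORMALIZER:
        raise FloatingPointError(
            "posterior normalizer underflows; the conditioning history is "
            "implausible under the fitted model (try conditioning on fewer "
            "intervals)"
        )
    accept = np.exp(log_norm)
    Lu = np.linalg.cholesky(S_u)
    if accept >= REJECTION_MIN_ACCEPT:
        draws = np.empty((0, post.K))
        batch = max(64, int(1.5 * L / accept))
        while draws.shape[0] < L:
            cand = m_u + rng.standard_normal((batch, post.K)) @ Lu.T
            draws = np.vstack([draws, cand[np.all(cand >= 0, axis=1)]])
        u = draws[:L]
    else:
        u = _gibbs_orthant(m_u, S_u, L, rng)

    # b | u is Gaussian: cov(b, u) = Omega D'
    cross = post.Omega @ post.D.T  # (d, K)
    gain = np.linalg.solve(S_u, cross.T).T  # (d, K)
    cond_cov = post.Omega - gain @ cross.T
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    w, V = np.linalg.eigh(cond_cov)
    root = V * np.sqrt(np.maximum(w, 0.0))
    b = post.mu + (u - m_u) @ gain.T + rng.standard_normal((L, d)) @ root.T
    return b


def _posterior_mode(post: SkewNormalPosterior, start: np.ndarray) -> np.ndarray:
    from scipy.optimize import minimize

    res = minimize(lambda b: -float(post.logpdf(b)[0]), start, method="BFGS")
    return res.x


def _summarize(post, samples, summary):
    if summary == "median":
        return np.median(samples, axis=0)
    if summary == "mean":
        return samples.mean(axis=0)
    if summary == "mode":
        return _posterior_mode(post, np.median(samples, axis=0))
    raise ValueError(f"unknown summary {summary!r}; expected mean, median or mode")


def predict_survival(
    fit,
    subject: SubjectRecord,
    r: int,
    s: int,
    L: int = 200,
    summary: str = "median",
    seed: Optional[int] = None,
    average: bool = False,
) -> PredictionResult:
    """Predicted probability of surviving through interval ``s`` given
    survival through ``r`` and the history up to ``t(r)``.

    ``fit`` is a :class:`~flexjm.estimation.FitResult` (or any object
    with ``params``, ``parameterization`` attributes).  By default the
    probit factors are evaluated at the posterior summary ``b_hat``;
    with ``average=True`` the product of factors is instead averaged
    over the posterior draws.
    """
    params: ModelParams = fit.params
    part: TimePartition = fit.partition if hasattr(fit, "partition") else None
    if part is None:
        raise ValueError("fit object must carry the time partition")
    if not r < s <= part.M:
        raise ValueError(f"need r < s <= M, got r={r}, s={s}, M={part.M}")
    if subject.x_surv is None or subject.x_surv.shape[0] < s:
        raise ValueError(
            f"subject {subject.id}: survival covariates missing for intervals up to {s}"
        )
    parameterization = getattr(fit, "parameterization", "intercept_slope")
    post = posterior_b(params, subject, r, part, parameterization)
    samples = sample_posterior(post, L, seed=seed)
    b_hat = _summarize(post, samples, summary)

    d = params.beta.size
    loads = []
    offs = []
    for k in range(r + 1, s + 1):
        A = _assoc_rows(k, part, parameterization, d)
        load = params.gamma_for_interval(k) @ A
        loads.append(load)
        offs.append(subject.x_surv[k - 1] @ params.alpha_tilde + load @ params.beta)
    loads = np.asarray(loads)
    offs = np.asarray(offs)
    if average:
        eta = offs + samples @ loads.T  # (L, s-r)
        pi = float(np.mean(np.prod(ndtr(eta), axis=1)))
    else:
        eta = offs + loads @ b_hat
        pi = float(np.prod(ndtr(eta)))
    return PredictionResult(
        pi=pi, samples_b=samples, b_hat=b_hat, r=r, s=s, seed=seed, summary=summary
    )
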