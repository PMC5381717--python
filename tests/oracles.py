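"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form likelihood path: the
integrand of each subject's marginal likelihood is written out directly
(Gaussian longitudinal density x probit survival factors x Gaussian
random-effects prior) and integrated numerically.
"""

import numpy as np
from scipy.special import logsumexp, ndtr

from flexjm.timegrid import association_design, design_matrix


def _mvn_logpdf(x, mean, cov):
    x = np.atleast_2d(x)
    L = np.linalg.cholesky(cov)
    r = np.linalg.solve(L, (x - mean).T).T
    return -0.5 * (
        x.shape[1] * np.log(2 * np.pi)
        + 2 * np.sum(np.log(np.diag(L)))
        + np.sum(r * r, axis=1)
    )


def raw_log_integrand(b, subject, params, part, parameterization="intercept_slope"):
    """log of f(Y|b) f(s, delta|b) f(b), vectorized over rows of b."""
    b = np.atleast_2d(b)
    d = b.shape[1]
    # prior
    Sigma = np.zeros((d, d))
    Sigma[0, 0] = params.sigma0**2
    Sigma[1, 1] = params.sigma1**2
    Sigma[0, 1] = Sigma[1, 0] = params.rho * params.sigma0 * params.sigma1
    if d > 2:
        Sigma[2:, 2:] = params.sigma2**2 * np.eye(d - 2)
    out = _mvn_logpdf(b, np.zeros(d), Sigma)
    # longitudinal density
    if subject.n_obs:
        B = design_matrix(subject.times, part).values
        mu = B @ params.beta + b @ B.T
        if params.alpha.size:
            mu = mu + subject.x_long @ params.alpha
        out = out + np.sum(
            -0.5 * np.log(2 * np.pi * params.sigma_eps**2)
            - 0.5 * ((subject.y - mu) / params.sigma_eps) ** 2,
            axis=1,
        )
    # survival factors
    for r in range(1, subject.s_star + 1):
        A = association_design(r, part, parameterization)
        g = params.gamma_for_interval(r)
        eta = subject.x_surv[r - 1] @ params.alpha_tilde + (g @ A) @ (
            params.beta[:, None] + b.T
        )
        if r == subject.s_star and subject.delta == 1:
            out = out + np.log(ndtr(-eta))
        else:
            out = out + np.log(ndtr(eta))
    return out


def _posterior_center(subject, params, part):
    """Rough Gaussian centering for importance quadrature (ridge formulas,
    independent of the package's factorized-covariance implementation)."""
    d = params.beta.size
    Sigma = np.zeros((d, d))
    Sigma[0, 0] = params.sigma0**2
    Sigma[1, 1] = params.sigma1**2
    Sigma[0, 1] = Sigma[1, 0] = params.rho * params.sigma0 * params.sigma1
    if d > 2:
        Sigma[2:, 2:] = params.sigma2**2 * np.eye(d - 2)
    if subject.n_obs == 0:
        return np.zeros(d), Sigma
    B = design_matrix(subject.times, part).values
    prec = np.linalg.inv(Sigma) + B.T @ B / params.sigma_eps**2
    cov = np.linalg.inv(prec)
    resid = subject.y - B @ params.beta
    if params.alpha.size:
        resid = resid - subject.x_long @ params.alpha
    mean = cov @ (B.T @ resid) / params.sigma_eps**2
    return mean, cov


def gh_loglik_oracle(
    subject, params, part, parameterization="intercept_slope", n_nodes=12
):
    """Brute-force log marginal likelihood by tensor Gauss-Hermite quadrature
    with Gaussian importance centering."""
    d = params.beta.size
    mean, cov = _posterior_center(subject, params, part)
    cov = cov * 1.7  # widen to cover the probit-induced skew
    C = np.linalg.cholesky(cov)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.meshgrid(*([nodes] * d), indexing="ij")
    Z = np.column_stack([g.ravel() for g in grids])
    logW = np.sum(
        np.log(np.array(np.meshgrid(*([weights] * d), indexing="ij")))
        .reshape(d, -1)
        .T,
        axis=1,
    )
    bs = mean + np.sqrt(2.0) * Z @ C.T
    log_ratio = raw_log_integrand(bs, subject, params, part, parameterization) - _mvn_logpdf(
        bs, mean, cov
    )
    # E_{N(mean,cov)}[g/N] approximated with GH: pi^{-d/2} sum w_k ratio_k
    return float(logsumexp(logW + log_ratio) - 0.5 * d * np.log(np.pi))


def grid_posterior_moments(post, n_nodes=70, half_width=6.0):
    """Moments and marginal CDF grids of a 3-dimensional skew-normal
    posterior by dense tensor-grid integration of the unnormalized density."""
    d = post.mu.size
    assert d == 3, "grid oracle is sized for 3-dimensional toys"
    sds = np.sqrt(np.diag(post.Omega))
    axes = [
        np.linspace(post.mu[j] - half_width * sds[j], post.mu[j] + half_width * sds[j], n_nodes)
        for j in range(d)
    ]
    steps = [a[1] - a[0] for a in axes]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([g.ravel() for g in grids])
    logp = _mvn_logpdf(pts, post.mu, post.Omega)
    if post.K:
        logp = logp + np.sum(np.log(ndtr(pts @ post.D.T + post.c)), axis=1)
    w = np.exp(logp - logp.max())
    Zmass = w.sum()
    mean = pts.T @ w / Zmass
    centered = pts - mean
    cov = (centered * w[:, None]).T @ centered / Zmass
    # per-coordinate marginal CDFs on the axis grids
    wcube = w.reshape((n_nodes,) * d)
    cdfs = []
    for j in range(d):
        marg = wcube.sum(axis=tuple(k for k in range(d) if k != j))
        # midpoint-rule mass sits centered on each node: the CDF at node j
        # includes only half of that node's own cell
        cdf = (np.cumsum(marg) - 0.5 * marg) / marg.sum()
        cdfs.append((axes[j], cdf))
    norm = Zmass * np.prod(steps) * np.exp(logp.max())
    return mean, cov, cdfs, norm
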