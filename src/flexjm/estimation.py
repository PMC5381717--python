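"""Maximum penalized likelihood fitting and smoothing selection.

The full parameter vector is maximized by quasi-Newton iteration on the
unconstrained scale (log standard deviations, Fisher-z correlation).
Standard errors come from the inverse of the numerically differentiated
observed information at the optimum, delta-method mapped back to the
natural scale.  The smoothing parameter is chosen by minimizing
``AIC(lambda) = -2 log L + 2 df(lambda) + 2 dim(theta_tilde)`` over a
grid, where ``df(lambda)`` is the trace of the ridge-type smoother
matrix of the population spline and ``theta_tilde`` excludes the
penalized spline coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import (
    JointDataset,
    ModelParams,
    ParamLayout,
    from_unconstrained,
    to_unconstrained,
)
from .likelihood import LikelihoodCore, N_POINTS_EXACT, N_POINTS_FIT, build_sigma
from .timegrid import design_matrix

__all__ = [
    "FitResult",
    "fit",
    "df_lambda",
    "aic",
    "select_lambda",
    "fit_longitudinal",
    "LongitudinalFit",
]

logger = logging.getLogger(__name__)

DEFAULT_SETTINGS = {
    "maxiter": 500,
    "ftol": 1e-9,
    "gtol": 1e-5,
    "n_points": N_POINTS_FIT,
    "hess_step": 1e-4,
}


@dataclass
class FitResult:
    params: ModelParams
    layout: ParamLayout
    loglik: float  # unpenalized, at the estimate
    lam: float
    converged: bool
    n_iter: int
    se: Optional[np.ndarray] = None  # natural scale, aligned with param_names
    se_unconstrained: Optional[np.ndarray] = None
    df_lambda: Optional[float] = None
    aic: Optional[float] = None
    parameterization: str = "intercept_slope"
    param_names: list = field(default_factory=list)
    partition: object = None

    def summary(self) -> pd.DataFrame:
        est = _natural_values(self.params)
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": est,
                "se": self.se if self.se is not None else np.full(len(est), np.nan),
            }
        )


def _param_names(layout: ParamLayout, data: JointDataset) -> list:
    names = [f"alpha[{n}]" for n in data.covariate_names_long[: layout.p]]
    names += [f"beta[{l}]" for l in range(layout.n_basis)]
    surv = data.covariate_names_surv or [str(j) for j in range(layout.q_tilde)]
    names += [f"alpha_tilde[{n}]" for n in surv[: layout.q_tilde]]
    if layout.gamma_time_varying:
        names += [f"gamma[{r},{j}]" for r in range(1, layout.M + 1) for j in range(layout.q)]
    else:
        names += [f"gamma[{j}]" for j in range(layout.q)]
    names += ["sigma_eps", "sigma0", "sigma1"]
    if layout.has_sigma2:
        names.append("sigma2")
    names.append("rho")
    return names


def _natural_values(params: ModelParams) -> np.ndarray:
    pieces = [params.alpha, params.beta, params.alpha_tilde, params.gamma.ravel(),
              [params.sigma_eps, params.sigma0, params.sigma1]]
    if params.sigma2 is not None:
        pieces.append([params.sigma2])
    pieces.append([params.rho])
    return np.concatenate([np.asarray(x, dtype=float).ravel() for x in pieces])


def _delta_jacobian(params: ModelParams) -> np.ndarray:
    """d(natural)/d(unconstrained), diagonal."""
    n_reg = params.alpha.size + params.beta.size + params.alpha_tilde.size + params.gamma.size
    sds = [params.sigma_eps, params.sigma0, params.sigma1]
    if params.sigma2 is not None:
        sds.append(params.sigma2)
    return np.concatenate([np.ones(n_reg), sds, [1.0 - params.rho**2]])


def _fd_hessian(f, x: np.ndarray, rel_step: float) -> np.ndarray:
    """Central finite-difference Hessian."""
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def stacked_basis(data: JointDataset) -> np.ndarray:
    """All subjects' truncated-basis rows stacked (the df(lambda) design)."""
    blocks = [
        design_matrix(s.times, data.partition).values
        for s in data.subjects
        if s.n_obs
    ]
    if not blocks:
        return np.empty((0, data.partition.M + 1))
    return np.vstack(blocks)


def df_lambda(lam: float, Btilde: np.ndarray, sigma_eps_hat: float) -> float:
    """Effective degrees of freedom of the penalized population spline.

    ``tr{(B'B + 2 lambda sigma_eps^2 D)^{-1} B'B}`` with ``D`` selecting
    the truncated-basis columns; evaluated via a linear solve.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    BtB = Btilde.T @ Btilde
    d = BtB.shape[0]
    D = np.eye(d)
    D[0, 0] = D[1, 1] = 0.0
    A = BtB + 2.0 * lam * sigma_eps_hat**2 * D
    try:
        return float(np.trace(np.linalg.solve(A, BtB)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular df(lambda) system: {exc}") from exc


def aic(loglik: float, df: float, layout: ParamLayout) -> float:
    """``-2 log L + 2 df(lambda) + 2 dim(theta_tilde)``."""
    return -2.0 * loglik + 2.0 * df + 2.0 * layout.dim_theta_tilde()


# ---------------------------------------------------------------------------
# Longitudinal-only penalized fit (stage 1 of the two-stage approach and the
# default source of starting values)


@dataclass
class LongitudinalFit:
    params: ModelParams  # survival entries zeroed
    loglik: float  # penalized longitudinal log likelihood at the optimum
    converged: bool


def _long_groups(data: JointDataset, n_basis: int):
    """Stack subjects with equal numbers of measurements for batched GLS."""
    groups = {}
    for s in data.subjects:
        if s.n_obs:
            groups.setdefault(s.n_obs, []).append(s)
    out = []
    p = len(data.covariate_names_long)
    for n, subs in groups.items():
        if n_basis == data.partition.M + 1:
            B = np.stack([design_matrix(s.times, data.partition).values for s in subs])
        else:
            B = np.stack(
                [np.column_stack([np.ones(n), s.times]) for s in subs]
            )
        U = (
            np.concatenate([np.stack([s.x_long for s in subs]), B], axis=2)
            if p
            else B
        )
        y = np.stack([s.y for s in subs])
        out.append((n, B, U, y))
    return out


def _long_profile(groups, lam, n_basis, p, M, var):
    """Profile (alpha, beta) out by penalized GLS at fixed variance params.

    ``var`` = (log sigma_eps, log sigma0, log sigma1[, log sigma2], z(rho)).
    Returns (negative profiled penalized loglik, theta_hat).
    """
    has_s2 = n_basis > 2
    sigma_eps, sigma0, sigma1 = np.exp(var[:3])
    sigma2 = float(np.exp(var[3])) if has_s2 else None
    rho = float(np.tanh(var[-1]))
    dummy = ModelParams(
        alpha=np.empty(0), beta=np.zeros(n_basis), alpha_tilde=np.zeros(1),
        gamma=np.zeros(1), sigma_eps=sigma_eps, sigma0=sigma0, sigma1=sigma1,
        rho=rho, sigma2=sigma2,
    )
    Sigma = build_sigma(dummy, M).Sigma
    d = n_basis + p
    XtCX = np.zeros((d, d))
    XtCy = np.zeros(d)
    quad_const = 0.0
    logdet = 0.0
    n_tot = 0
    for n, B, U, y in groups:
        C = sigma_eps**2 * np.eye(n) + np.einsum("gnd,de,gme->gnm", B, Sigma, B)
        L = np.linalg.cholesky(C)
        Uw = np.linalg.solve(L, U)
        yw = np.linalg.solve(L, y[..., None])[..., 0]
        XtCX += np.einsum("gni,gnj->ij", Uw, Uw)
        XtCy += np.einsum("gni,gn->i", Uw, yw)
        quad_const += float(np.sum(yw * yw))
        logdet += 2 * float(np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1))))
        n_tot += n * B.shape[0]
    P = np.zeros((d, d))
    if n_basis > 2:
        P[p + 2 :, p + 2 :] = np.eye(n_basis - 2)
    theta = np.linalg.solve(XtCX + 2 * lam * P, XtCy)
    quad = quad_const - 2 * theta @ XtCy + theta @ XtCX @ theta
    obj = 0.5 * (n_tot * np.log(2 * np.pi) + logdet + quad) + lam * theta[p + 2 :] @ theta[p + 2 :]
    return obj, theta


def fit_longitudinal(
    data: JointDataset, lam: float = 0.0, n_basis: Optional[int] = None
) -> LongitudinalFit:
    """Penalized ML fit of the longitudinal sub-model alone.

    The regression coefficients are profiled out in closed form; the
    variance parameters are optimized numerically.
    """
    d = data.partition.M + 1 if n_basis is None else n_basis
    p = len(data.covariate_names_long)
    M = data.partition.M
    has_s2 = d > 2
    groups = _long_groups(data, d)
    y_all = np.concatenate([s.y for s in data.subjects if s.n_obs])
    s_guess = max(np.std(y_all), 1e-3)
    x0 = np.log([s_guess * 0.6, s_guess * 0.8, s_guess * 0.8])
    if has_s2:
        x0 = np.append(x0, np.log(s_guess * 0.6))
    x0 = np.append(x0, 0.0)

    def obj(v):
        try:
            return _long_profile(groups, lam, d, p, M, v)[0]
        except np.linalg.LinAlgError:
            return 1e10

    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 1000})
    _, theta = _long_profile(groups, lam, d, p, M, res.x)
    sigma_eps, sigma0, sigma1 = np.exp(res.x[:3])
    sigma2 = float(np.exp(res.x[3])) if has_s2 else None
    q_tilde = len(data.covariate_names_surv) or 1
    params = ModelParams(
        alpha=theta[:p],
        beta=theta[p:],
        alpha_tilde=np.zeros(q_tilde),
        gamma=np.zeros(2),
        sigma_eps=float(sigma_eps),
        sigma0=float(sigma0),
        sigma1=float(sigma1),
        rho=float(np.tanh(res.x[-1])),
        sigma2=sigma2,
    )
    return LongitudinalFit(params=params, loglik=-float(res.fun), converged=bool(res.success))


def _auto_init(
    data: JointDataset, lam: float, parameterization: str, n_basis: int
) -> ModelParams:
    """Two-stage starting values: longitudinal fit, then a probit fit of the
    person-interval expansion on empirical Bayes trajectories."""
    from .comparators import _stage2_probit  # deferred: comparators imports us

    stage1 = fit_longitudinal(data, lam=lam, n_basis=n_basis)
    try:
        alpha_tilde, gamma = _stage2_probit(data, stage1.params, parameterization, n_basis)
    except Exception as exc:  # pragma: no cover - degenerate separation etc.
        logger.warning("stage-2 probit init failed (%s); using zeros", exc)
        q = 2 if parameterization == "intercept_slope" else 1
        alpha_tilde = np.zeros(len(data.covariate_names_surv) or 1)
        gamma = np.zeros(q)
    out = stage1.params.copy()
    out.alpha_tilde = np.asarray(alpha_tilde, dtype=float)
    out.gamma = np.asarray(gamma, dtype=float)
    return out


def fit(
    data: JointDataset,
    lam: float,
    init: ModelParams | str = "auto",
    parameterization: str = "intercept_slope",
    n_basis: Optional[int] = None,
    settings: Optional[dict] = None,
    compute_se: bool = True,
    gamma_time_varying: bool = False,
) -> FitResult:
    """Maximize the penalized joint likelihood.

    ``n_basis=2`` restricts the individual-level spline to the random
    intercept + slope model (no truncated columns, no ``sigma2``).
    """
    opts = dict(DEFAULT_SETTINGS)
    opts.update(settings or {})
    d = data.partition.M + 1 if n_basis is None else n_basis
    if init == "auto":
        init = _auto_init(data, lam, parameterization, d)
    if gamma_time_varying and init.gamma.ndim == 1:
        init = init.copy()
        init.gamma = np.tile(init.gamma, (data.partition.M, 1))
    layout = init.layout(data.partition.M, gamma_time_varying)
    core = LikelihoodCore(
        data, parameterization=parameterization, n_basis=d, n_points=opts["n_points"]
    )

    def objective(v):
        try:
            return core.penalized_negloglik(from_unconstrained(v, layout), lam)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e10

    x0 = to_unconstrained(init)
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": opts["maxiter"],
            "ftol": opts["ftol"],
            "gtol": opts["gtol"],
        },
    )
    params_hat = from_unconstrained(res.x, layout)
    if not res.success:
        logger.warning("optimizer did not converge: %s", res.message)

    # reporting-accuracy unpenalized log likelihood at the estimate
    core_exact = LikelihoodCore(
        data, parameterization=parameterization, n_basis=d, n_points=N_POINTS_EXACT
    )
    loglik = core_exact.loglik(params_hat)

    result = FitResult(
        params=params_hat,
        layout=layout,
        loglik=loglik,
        lam=lam,
        converged=bool(res.success),
        n_iter=int(res.nit),
        parameterization=parameterization,
        param_names=_param_names(layout, data),
        partition=data.partition,
    )
    if d == data.partition.M + 1:
        Btilde = stacked_basis(data)
        result.df_lambda = df_lambda(lam, Btilde, params_hat.sigma_eps)
        result.aic = aic(loglik, result.df_lambda, layout)
    if compute_se:
        try:
            H = _fd_hessian(objective, res.x, opts["hess_step"])
            cov = np.linalg.inv(H)
            var_u = np.diag(cov)
            if np.any(var_u <= 0):
                warnings.warn(
                    "observed information is not positive definite; "
                    "standard errors unavailable for some parameters"
                )
            se_u = np.sqrt(np.where(var_u > 0, var_u, np.nan))
            result.se_unconstrained = se_u
            result.se = se_u * _delta_jacobian(params_hat)
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; standard errors unavailable")
    return result


def select_lambda(
    data: JointDataset,
    grid,
    init: ModelParams | str = "auto",
    parameterization: str = "intercept_slope",
    settings: Optional[dict] = None,
) -> tuple:
    """Fit at each grid value (warm-started) and pick the AIC minimizer.

    Returns ``(best_fit, table)`` where the table has one row per grid
    value with the log likelihood, df(lambda) and AIC.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    rows = []
    fits = {}
    current_init = init
    for lam in grid:
        try:
            f = fit(
                data, lam, init=current_init, parameterization=parameterization,
                settings=settings, compute_se=False,
            )
            fits[lam] = f
            current_init = f.params
            rows.append(
                {"lambda": lam, "loglik": f.loglik, "df": f.df_lambda,
                 "aic": f.aic, "converged": f.converged, "failed": False}
            )
        except Exception as exc:
            logger.warning("fit at lambda=%g failed: %s", lam, exc)
            rows.append(
                {"lambda": lam, "loglik": np.nan, "df": np.nan, "aic": np.nan,
                 "converged": False, "failed": True}
            )
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise RuntimeError("all lambda-grid fits failed")
    best_lam = float(ok.loc[ok["aic"].idxmin(), "lambda"])
    best = fits[best_lam]
    return best, table
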