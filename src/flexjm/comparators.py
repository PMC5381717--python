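"""Alternative dynamic-prediction methods and the prediction-error evaluator.

Implements the benchmark methods a flexible joint model is usually
compared against:

* ``tvc`` — discrete-time probit survival model with the last observed
  longitudinal outcome carried forward as a time-varying covariate;
* ``two_stage`` — penalized linear mixed model fitted to the
  longitudinal data alone, empirical Bayes trajectories plugged into a
  separate probit survival model;
* ``ri_rs_joint`` — joint model restricted to a random intercept and
  slope (no truncated basis columns);
* ``pspline_joint`` — the full model (delegates to
  :mod:`flexjm.estimation`);
* ``gold_standard`` — predictions computed with the true simulated
  random effects and true parameters.

All methods consume identical datasets and survival-covariate builders
and share one person-interval expansion, so performance differences
reflect the method, not the plumbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr

from .data import JointDataset, ModelParams, SubjectRecord
from .estimation import FitResult, fit, fit_longitudinal
from .likelihood import _assoc_rows, gaussian_conjugacy
from .prediction import posterior_b, sample_posterior, _summarize
from .timegrid import TimePartition

__all__ = [
    "ComparatorFit",
    "person_interval_table",
    "fit_tvc",
    "fit_two_stage",
    "fit_ri_rs_joint",
    "fit_pspline_joint",
    "gold_standard",
    "predict_pi",
    "prediction_error",
]

logger = logging.getLogger(__name__)

METHODS = ("tvc", "two_stage", "ri_rs_joint", "pspline_joint", "gold_standard")


@dataclass
class ComparatorFit:
    method: str
    partition: TimePartition
    parameterization: str = "intercept_slope"
    params: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")


def person_interval_table(data: JointDataset) -> pd.DataFrame:
    """One row per subject-interval at risk.

    ``survive`` is 1 for every interval the subject passed through and 0
    in the terminal interval when the event occurred; a subject with
    ``s_star = s`` contributes exactly ``s`` rows.
    """
    rows = []
    q_tilde = data.subjects[0].x_surv.shape[1] if data.subjects else 0
    for i, s in enumerate(data.subjects):
        if s.x_surv is None:
            raise ValueError(f"subject {s.id}: survival covariates not built")
        for r in range(1, s.s_star + 1):
            row = {"subject_index": i, "id": s.id, "r": r,
                   "survive": 0 if (r == s.s_star and s.delta == 1) else 1}
            for j in range(q_tilde):
                row[f"xs{j}"] = s.x_surv[r - 1, j]
            rows.append(row)
    return pd.DataFrame(rows)


def _fit_probit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Probit()))
    return np.asarray(model.fit().params)


def _last_observed(subject: SubjectRecord, t: float) -> Optional[float]:
    """Most recent outcome at or before time ``t`` (None if no data)."""
    idx = np.nonzero(subject.times <= t + 1e-12)[0]
    if idx.size:
        return float(subject.y[idx[-1]])
    if subject.n_obs:
        return float(subject.y[0])  # fall back to the earliest measurement
    return None


# ---------------------------------------------------------------------------
# Time-varying-covariate survival model


def fit_tvc(data: JointDataset) -> ComparatorFit:
    """Probit survival model with the last observed outcome carried forward."""
    table = person_interval_table(data)
    part = data.partition
    ylast = np.empty(len(table))
    keep = np.ones(len(table), dtype=bool)
    for row_i, (si, r) in enumerate(zip(table["subject_index"], table["r"])):
        subj = data.subjects[si]
        val = _last_observed(subj, float(part.boundaries[r - 1]))
        if val is None:
            keep[row_i] = False
        else:
            ylast[row_i] = val
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("tvc: dropping %d person-intervals with no outcome data", n_drop)
    q_tilde = data.subjects[0].x_surv.shape[1]
    X = np.column_stack(
        [table[[f"xs{j}" for j in range(q_tilde)]].to_numpy(), ylast]
    )[keep]
    coef = _fit_probit(X, table["survive"].to_numpy()[keep])
    return ComparatorFit(
        method="tvc",
        partition=part,
        params={"alpha_tilde": coef[:q_tilde], "gamma_y": float(coef[q_tilde])},
    )


# ---------------------------------------------------------------------------
# Two-stage approach


def _eb_trajectory_terms(
    data_or_part, subject: SubjectRecord, long_params: ModelParams,
    parameterization: str, t_max: Optional[float] = None,
):
    """Association terms W_r applied to beta + EB(b) for all intervals.

    The empirical Bayes estimate conditions on the longitudinal data
    only (never on survival), truncated at ``t_max`` when given.
    """
    part = data_or_part if isinstance(data_or_part, TimePartition) else data_or_part.partition
    hist = subject if t_max is None else subject.truncated(t_max)
    b_hat = gaussian_conjugacy(hist, long_params, part).mu_post
    d = long_params.beta.size
    M = part.M
    out = np.empty((M, _assoc_rows(1, part, parameterization, d).shape[0]))
    for r in range(1, M + 1):
        A = _assoc_rows(r, part, parameterization, d)
        out[r - 1] = A @ (long_params.beta + b_hat)
    return out, b_hat


def _stage2_probit(
    data: JointDataset, long_params: ModelParams, parameterization: str,
    n_basis: Optional[int] = None,
):
    """Probit survival fit on the person-interval expansion with empirical
    Bayes trajectory terms as covariates; returns (alpha_tilde, gamma)."""
    table = person_interval_table(data)
    q_tilde = data.subjects[0].x_surv.shape[1]
    W_all = {}
    for si in table["subject_index"].unique():
        W_all[si], _ = _eb_trajectory_terms(
            data.partition, data.subjects[si], long_params, parameterization
        )
    W = np.vstack(
        [W_all[si][r - 1] for si, r in zip(table["subject_index"], table["r"])]
    )
    X = np.column_stack([table[[f"xs{j}" for j in range(q_tilde)]].to_numpy(), W])
    coef = _fit_probit(X, table["survive"].to_numpy())
    return coef[:q_tilde], coef[q_tilde:]


def fit_two_stage(data: JointDataset, lam: float = 0.0) -> ComparatorFit:
    """Longitudinal-only penalized fit, then a probit survival fit on the
    empirical Bayes trajectories."""
    stage1 = fit_longitudinal(data, lam=lam)
    if not stage1.converged:
        raise RuntimeError("stage-1 longitudinal fit did not converge")
    alpha_tilde, gamma = _stage2_probit(data, stage1.params, "intercept_slope")
    return ComparatorFit(
        method="two_stage",
        partition=data.partition,
        params={
            "long_params": stage1.params,
            "alpha_tilde": np.asarray(alpha_tilde),
            "gamma": np.asarray(gamma),
        },
        provenance={"lambda": lam},
    )


# ---------------------------------------------------------------------------
# Joint models


def fit_ri_rs_joint(data: JointDataset, settings: Optional[dict] = None,
                    compute_se: bool = False) -> ComparatorFit:
    """Joint model with random intercept and slope only (basis {1, t})."""
    res = fit(data, lam=0.0, n_basis=2, settings=settings, compute_se=compute_se)
    return ComparatorFit(
        method="ri_rs_joint", partition=data.partition, params={"fit": res}
    )


def fit_pspline_joint(data: JointDataset, lam: float, settings: Optional[dict] = None,
                      compute_se: bool = False) -> ComparatorFit:
    res = fit(data, lam=lam, settings=settings, compute_se=compute_se)
    return ComparatorFit(
        method="pspline_joint", partition=data.partition, params={"fit": res},
        provenance={"lambda": lam},
    )


def gold_standard(true_params: ModelParams, truth: pd.DataFrame,
                  partition: TimePartition,
                  parameterization: str = "intercept_slope") -> ComparatorFit:
    """Reference predictor using the simulated coefficients and truth."""
    d = true_params.beta.size
    b_cols = [f"b{j}" for j in range(d)]
    b_by_id = {row["id"]: np.array([row[c] for c in b_cols])
               for _, row in truth.iterrows()}
    return ComparatorFit(
        method="gold_standard", partition=partition,
        parameterization=parameterization,
        params={"true_params": true_params, "b_by_id": b_by_id},
    )


# ---------------------------------------------------------------------------
# Prediction dispatch


def _phi_curve(params: ModelParams, subject: SubjectRecord, part: TimePartition,
               parameterization: str, b: np.ndarray, r: int, s_max: int) -> np.ndarray:
    """Cumulative products of survival factors for s = r+1 .. s_max."""
    d = params.beta.size
    pis = np.empty(s_max - r)
    acc = 1.0
    for k in range(r + 1, s_max + 1):
        A = _assoc_rows(k, part, parameterization, d)
        load = params.gamma_for_interval(k) @ A
        eta = subject.x_surv[k - 1] @ params.alpha_tilde + load @ (params.beta + b)
        acc *= float(ndtr(eta))
        pis[k - r - 1] = acc
    return pis


def predict_pi(cfit: ComparatorFit, subject: SubjectRecord, r: int, s_list,
               L: int = 200, seed: Optional[int] = None,
               summary: str = "median", average: bool = False) -> np.ndarray:
    """Predicted conditional survival probabilities at horizons ``s_list``.

    ``s_list`` must be increasing with ``r < s <= M``; one posterior
    draw set is shared across horizons.  For the joint methods,
    ``average=True`` replaces the plug-in at the posterior summary with
    the posterior mean of the survival-factor product (the calibrated
    predictor of the gold-standard probability).
    """
    part = cfit.partition
    s_list = list(s_list)
    s_max = max(s_list)
    if not all(r < s <= part.M for s in s_list):
        raise ValueError(f"horizons {s_list} must satisfy r < s <= M={part.M}")
    m = cfit.method
    if m == "tvc":
        ylast = _last_observed(subject, float(part.boundaries[r]))
        if ylast is None:
            raise ValueError(f"subject {subject.id}: no outcome data for tvc prediction")
        at = cfit.params["alpha_tilde"]
        gy = cfit.params["gamma_y"]
        acc = 1.0
        out = np.empty(s_max - r)
        for k in range(r + 1, s_max + 1):
            acc *= float(ndtr(subject.x_surv[k - 1] @ at + gy * ylast))
            out[k - r - 1] = acc
        curve = out
    elif m == "two_stage":
        lp = cfit.params["long_params"]
        terms, b_hat = _eb_trajectory_terms(
            part, subject, lp, cfit.parameterization, t_max=float(part.boundaries[r])
        )
        at = cfit.params["alpha_tilde"]
        g = cfit.params["gamma"]
        acc = 1.0
        curve = np.empty(s_max - r)
        for k in range(r + 1, s_max + 1):
            acc *= float(ndtr(subject.x_surv[k - 1] @ at + g @ terms[k - 1]))
            curve[k - r - 1] = acc
    elif m in ("ri_rs_joint", "pspline_joint"):
        res: FitResult = cfit.params["fit"]
        post = posterior_b(res.params, subject, r, part, res.parameterization)
        samples = sample_posterior(post, L, seed=seed)
        if average:
            params = res.params
            d = params.beta.size
            acc = np.ones(L)
            curve = np.empty(s_max - r)
            for k in range(r + 1, s_max + 1):
                A = _assoc_rows(k, part, res.parameterization, d)
                load = params.gamma_for_interval(k) @ A
                eta = subject.x_surv[k - 1] @ params.alpha_tilde + (
                    params.beta + samples
                ) @ load
                acc = acc * ndtr(eta)
                curve[k - r - 1] = acc.mean()
        else:
            b_hat = _summarize(post, samples, summary)
            curve = _phi_curve(res.params, subject, part, res.parameterization,
                               b_hat, r, s_max)
    elif m == "gold_standard":
        b_true = cfit.params["b_by_id"][subject.id]
        curve = _phi_curve(cfit.params["true_params"], subject, part,
                           cfit.parameterization, b_true, r, s_max)
    else:  # pragma: no cover
        raise ValueError(m)
    return np.array([curve[s - r - 1] for s in s_list])


def prediction_error(
    fits,
    testset: JointDataset,
    truth: pd.DataFrame,
    r_grid,
    dt_grid,
    L: int = 200,
    seed: int = 0,
    true_params: Optional[ModelParams] = None,
    average: bool = True,
) -> pd.DataFrame:
    """Mean squared difference to the gold-standard predictor.

    For every method, prediction time ``r`` and window ``dt``, computes
    the mean over subjects at risk at ``r`` (observed ``s_star > r``) of
    ``(pi_method - pi_gold)^2``.  Rows with an empty risk set are
    flagged and not computed.

    By default the joint methods are scored with the posterior-averaged
    probability (``average=True``): against a squared-error criterion
    the calibrated predictor is the fair representative of each
    method's information content, whereas the plug-in at a posterior
    summary is over-dispersed whenever the posterior is wide.
    """
    part = testset.partition
    if true_params is None:
        raise ValueError("true_params is required to build the gold standard")
    gold = gold_standard(true_params, truth, part)
    methods = {f.method: f for f in fits}
    rows = []
    rng = np.random.default_rng(seed)
    for r in r_grid:
        s_list = [r + dt for dt in dt_grid if r + dt <= part.M]
        at_risk = [s for s in testset.subjects if s.s_star > r]
        if not at_risk or not s_list:
            for dt in dt_grid:
                for m in methods:
                    rows.append({"method": m, "r": r, "dt": dt, "mse": np.nan,
                                 "n_at_risk": len(at_risk), "flagged": True})
            continue
        sub_seeds = rng.integers(0, 2**31 - 1, size=len(at_risk))
        pi_gold = np.array([predict_pi(gold, s, r, s_list) for s in at_risk])
        for m, cfit in methods.items():
            pi_hat = np.array(
                [predict_pi(cfit, s, r, s_list, L=L, seed=int(sub_seeds[j]),
                            average=average)
                 for j, s in enumerate(at_risk)]
            )
            err = (pi_hat - pi_gold) ** 2
            for j, dt in enumerate(dt for dt in dt_grid if r + dt <= part.M):
                rows.append({"method": m, "r": r, "dt": dt,
                             "mse": float(err[:, j].mean()),
                             "n_at_risk": len(at_risk), "flagged": False})
    return pd.DataFrame(rows)
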