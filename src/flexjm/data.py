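"""Joint-dataset containers, covariate builders, parameter transforms and CSV I/O.

File dialect: comma-separated, header row, UTF-8, decimal point, missing
values as empty fields.  The longitudinal file has columns
``id, time, y, <covariates...>`` with time in original units; the
survival file has ``id, s_star, delta, <baseline covariates...>``.

Censoring semantics: a censored subject (``delta = 0``) with observed
interval ``s_star = s`` is taken to have survived through interval ``s``
(their likelihood contribution includes the survival factor for interval
``s``); users should code ``s_star`` accordingly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .timegrid import TimePartition, ASSOCIATION_TAGS

__all__ = [
    "SubjectRecord",
    "JointDataset",
    "ModelParams",
    "ParamLayout",
    "ModelConfig",
    "read_joint_dataset",
    "write_joint_dataset",
    "build_survival_covariates",
    "to_unconstrained",
    "from_unconstrained",
]

logger = logging.getLogger(__name__)


@dataclass
class SubjectRecord:
    """One subject's longitudinal history and discrete survival outcome."""

    id: object
    times: np.ndarray  # scaled measurement times, ascending
    y: np.ndarray
    x_long: np.ndarray  # (n_i, p) longitudinal covariates
    s_star: int  # observed interval in 1..M
    delta: int  # 1 = event, 0 = censored
    x_surv: Optional[np.ndarray] = None  # (M, q_tilde), filled by the builder
    baseline: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    def truncated(self, t_max: float) -> "SubjectRecord":
        """Copy keeping only measurements at times <= ``t_max``."""
        keep = self.times <= t_max + 1e-12
        return replace(
            self,
            times=self.times[keep],
            y=self.y[keep],
            x_long=self.x_long[keep],
        )


@dataclass
class JointDataset:
    subjects: list
    partition: TimePartition
    covariate_names_long: list = field(default_factory=list)
    covariate_names_surv: list = field(default_factory=list)
    baseline_names: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subjects)

    def validate(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids are not unique")
        M = self.partition.M
        for s in self.subjects:
            if not 1 <= s.s_star <= M:
                raise ValueError(f"subject {s.id}: s_star={s.s_star} outside 1..{M}")
            if s.delta not in (0, 1):
                raise ValueError(f"subject {s.id}: delta={s.delta} not in {{0,1}}")
            if s.times.size and np.any(np.diff(s.times) < 0):
                raise ValueError(f"subject {s.id}: measurement times not ascending")
            if s.times.size and s.times[-1] > self.partition.boundaries[s.s_star] + 1e-9:
                raise ValueError(
                    f"subject {s.id}: measurement after the end of the observed "
                    f"interval {s.s_star}"
                )
            if s.y.size != s.times.size:
                raise ValueError(f"subject {s.id}: y and times lengths differ")


@dataclass
class ParamLayout:
    """Shapes of the parameter vector for a given model configuration."""

    p: int  # longitudinal covariates
    n_basis: int  # spline coefficients (M+1, or 2 for the linear model)
    q_tilde: int  # survival covariates
    q: int  # association terms per interval
    gamma_time_varying: bool = False
    M: int = 0  # intervals (gamma rows when time-varying)
    has_sigma2: bool = True

    @property
    def n_gamma(self) -> int:
        return self.q * (self.M if self.gamma_time_varying else 1)

    @property
    def size(self) -> int:
        n_var = 4 if self.has_sigma2 else 3  # sigma_eps, sigma0, sigma1[, sigma2]
        return self.p + self.n_basis + self.q_tilde + self.n_gamma + n_var + 1

    def dim_theta_tilde(self) -> int:
        """Parameter count excluding the penalized spline coefficients.

        The two unpenalized spline coefficients (overall intercept and
        slope) are counted here.
        """
        n_var = 4 if self.has_sigma2 else 3
        n_beta_free = min(2, self.n_basis)
        return self.p + n_beta_free + self.q_tilde + self.n_gamma + n_var + 1


@dataclass
class ModelParams:
    """All model unknowns on their natural scale."""

    alpha: np.ndarray  # (p,)
    beta: np.ndarray  # (n_basis,)
    alpha_tilde: np.ndarray  # (q_tilde,)
    gamma: np.ndarray  # (q,) or (M, q)
    sigma_eps: float
    sigma0: float
    sigma1: float
    rho: float
    sigma2: Optional[float] = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha_tilde = np.atleast_1d(np.asarray(self.alpha_tilde, dtype=float))
        self.gamma = np.asarray(self.gamma, dtype=float)
        for name in ("sigma_eps", "sigma0", "sigma1"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma2 is not None and not self.sigma2 > 0:
            raise ValueError("sigma2 must be strictly positive when present")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")

    def gamma_for_interval(self, r: int) -> np.ndarray:
        """Association coefficients for interval ``r`` (1-based)."""
        if self.gamma.ndim == 2:
            return self.gamma[r - 1]
        return self.gamma

    def layout(self, M: int, gamma_time_varying: Optional[bool] = None) -> ParamLayout:
        tv = self.gamma.ndim == 2 if gamma_time_varying is None else gamma_time_varying
        q = self.gamma.shape[-1] if self.gamma.ndim else 1
        return ParamLayout(
            p=self.alpha.size,
            n_basis=self.beta.size,
            q_tilde=self.alpha_tilde.size,
            q=q,
            gamma_time_varying=tv,
            M=M,
            has_sigma2=self.sigma2 is not None,
        )

    def copy(self) -> "ModelParams":
        return ModelParams(
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            alpha_tilde=self.alpha_tilde.copy(),
            gamma=self.gamma.copy(),
            sigma_eps=self.sigma_eps,
            sigma0=self.sigma0,
            sigma1=self.sigma1,
            rho=self.rho,
            sigma2=self.sigma2,
        )


def _fisher_z(rho: float) -> float:
    return float(np.arctanh(rho))


def to_unconstrained(params: ModelParams) -> np.ndarray:
    """Pack parameters into an unconstrained real vector.

    Log transform on the standard deviations, Fisher z on the
    correlation, identity on regression coefficients.
    """
    pieces = [
        params.alpha.ravel(),
        params.beta.ravel(),
        params.alpha_tilde.ravel(),
        params.gamma.ravel(),
        [np.log(params.sigma_eps), np.log(params.sigma0), np.log(params.sigma1)],
    ]
    if params.sigma2 is not None:
        pieces.append([np.log(params.sigma2)])
    pieces.append([_fisher_z(params.rho)])
    v = np.concatenate([np.asarray(x, dtype=float).ravel() for x in pieces])
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite value in unconstrained parameter vector")
    return v


def from_unconstrained(v: np.ndarray, layout: ParamLayout) -> ModelParams:
    """Inverse of :func:`to_unconstrained` for a given layout."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite unconstrained parameter vector")
    if v.size != layout.size:
        raise ValueError(f"expected vector of length {layout.size}, got {v.size}")
    pos = 0

    def take(n):
        nonlocal pos
        out = v[pos : pos + n]
        pos += n
        return out

    alpha = take(layout.p)
    beta = take(layout.n_basis)
    alpha_tilde = take(layout.q_tilde)
    gamma = take(layout.n_gamma)
    if layout.gamma_time_varying:
        gamma = gamma.reshape(layout.M, layout.q)
    sigma_eps, sigma0, sigma1 = np.exp(take(3))
    sigma2 = float(np.exp(take(1)[0])) if layout.has_sigma2 else None
    rho = float(np.tanh(take(1)[0]))
    return ModelParams(
        alpha=alpha,
        beta=beta,
        alpha_tilde=alpha_tilde,
        gamma=gamma,
        sigma_eps=float(sigma_eps),
        sigma0=float(sigma0),
        sigma1=float(sigma1),
        rho=rho,
        sigma2=sigma2,
    )


# ---------------------------------------------------------------------------
# Model configuration


@dataclass
class ModelConfig:
    """Model/run configuration shared by the CLI and the library."""

    partition: TimePartition
    long_covariates: list = field(default_factory=list)
    surv_terms: list = field(default_factory=lambda: ["1"])
    standardize: dict = field(default_factory=dict)
    association: str = "intercept_slope"
    gamma_time_varying: bool = False
    lambda_grid: list = field(default_factory=lambda: list(np.geomspace(1e-3, 1e2, 16)))
    seed: int = 0
    optimizer: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.association not in ASSOCIATION_TAGS:
            raise ValueError(f"unknown association tag {self.association!r}")

    @property
    def q(self) -> int:
        return 2 if self.association == "intercept_slope" else 1

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        part = d["partition"]
        partition = TimePartition.from_original_boundaries(
            part["boundaries"], float(part.get("scale", 1.0))
        )
        return cls(
            partition=partition,
            long_covariates=list(d.get("longitudinal", {}).get("covariates", [])),
            surv_terms=list(d.get("survival", {}).get("terms", ["1"])),
            standardize=dict(d.get("survival", {}).get("standardize", {})),
            association=d.get("association", "intercept_slope"),
            gamma_time_varying=bool(d.get("gamma_time_varying", False)),
            lambda_grid=list(d.get("lambda_grid", np.geomspace(1e-3, 1e2, 16))),
            seed=int(d.get("seed", 0)),
            optimizer=dict(d.get("optimizer", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "partition": {
                "boundaries": [float(x) for x in self.partition.to_original(self.partition.boundaries)],
                "scale": float(self.partition.scale),
            },
            "longitudinal": {"covariates": list(self.long_covariates)},
            "survival": {
                "terms": list(self.surv_terms),
                "standardize": dict(self.standardize),
            },
            "association": self.association,
            "gamma_time_varying": self.gamma_time_varying,
            "lambda_grid": [float(v) for v in self.lambda_grid],
            "seed": self.seed,
            "optimizer": dict(self.optimizer),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Survival covariate builder

_POWER_RE = re.compile(r"^(?P<base>\w+)\^(?P<power>\d+)$")


def _surv_term_values(term: str, rstart: np.ndarray, baseline: dict, standardize: dict):
    """Evaluate one survival design term for all M intervals."""

    def baseline_value(name):
        if name not in baseline:
            raise KeyError(name)
        val = float(baseline[name])
        if name in standardize:
            tr = standardize[name]
            val = (val - float(tr.get("center", 0.0))) / float(tr.get("scale", 1.0))
        return val

    if term == "1":
        return np.ones_like(rstart)
    m = _POWER_RE.match(term)
    base, power = (m.group("base"), int(m.group("power"))) if m else (term, 1)
    if base == "rstart":
        return rstart**power
    try:
        return np.full_like(rstart, baseline_value(base) ** power)
    except KeyError:
        raise ValueError(
            f"unknown survival covariate term {term!r}: no baseline column "
            f"{base!r} and not a recognized time function"
        ) from None


def build_survival_covariates(dataset: JointDataset, config: ModelConfig) -> JointDataset:
    """Fill ``x_surv`` for every subject from the configured term list.

    Supported terms: ``"1"``, ``"rstart"`` (scaled time at the start of
    the interval), powers like ``"rstart^2"``, and baseline column names
    (optionally standardized via ``config.standardize`` as
    ``(value - center) / scale``).
    """
    rstart = dataset.partition.boundaries[:-1]
    for subj in dataset.subjects:
        cols = [
            _surv_term_values(t, rstart, subj.baseline, config.standardize)
            for t in config.surv_terms
        ]
        subj.x_surv = np.column_stack(cols)
    dataset.covariate_names_surv = list(config.surv_terms)
    return dataset


# ---------------------------------------------------------------------------
# Readers / writers


def read_joint_dataset(long_path, surv_path, config: ModelConfig) -> JointDataset:
    """Read and validate a joint dataset from the two CSV files.

    Times are converted to scaled units on input; longitudinal rows with
    a missing outcome are dropped (count logged).
    """
    long_df = pd.read_csv(long_path)
    surv_df = pd.read_csv(surv_path)
    for col in ("id", "time", "y"):
        if col not in long_df.columns:
            raise ValueError(f"longitudinal file missing required column {col!r}")
    for col in ("id", "s_star", "delta"):
        if col not in surv_df.columns:
            raise ValueError(f"survival file missing required column {col!r}")
    for col in config.long_covariates:
        if col not in long_df.columns:
            raise ValueError(f"longitudinal file missing covariate column {col!r}")

    n_missing = int(long_df["y"].isna().sum())
    if n_missing:
        logger.info("dropping %d longitudinal rows with missing outcome", n_missing)
        long_df = long_df.dropna(subset=["y"])

    if surv_df["id"].duplicated().any():
        raise ValueError("duplicate subject ids in the survival file")
    surv_ids = set(surv_df["id"])
    missing = set(long_df["id"]) - surv_ids
    if missing:
        raise ValueError(
            f"subjects {sorted(missing)!r} present in the longitudinal file "
            "but absent from the survival file"
        )

    baseline_names = [c for c in surv_df.columns if c not in ("id", "s_star", "delta")]
    part = config.partition
    groups = dict(iter(long_df.groupby("id", sort=False)))
    subjects = []
    for row in surv_df.itertuples(index=False):
        rec = row._asdict()
        sid = rec["id"]
        g = groups.get(sid)
        if g is None:
            times = np.empty(0)
            y = np.empty(0)
            x_long = np.empty((0, len(config.long_covariates)))
        else:
            times = part.from_original(g["time"].to_numpy(dtype=float))
            if np.any(np.diff(times) < 0):
                raise ValueError(f"subject {sid}: measurement times not ascending")
            y = g["y"].to_numpy(dtype=float)
            x_long = (
                g[config.long_covariates].to_numpy(dtype=float)
                if config.long_covariates
                else np.empty((len(g), 0))
            )
        subjects.append(
            SubjectRecord(
                id=sid,
                times=times,
                y=y,
                x_long=x_long,
                s_star=int(rec["s_star"]),
                delta=int(rec["delta"]),
                baseline={k: rec[k] for k in baseline_names},
            )
        )
    ds = JointDataset(
        subjects=subjects,
        partition=part,
        covariate_names_long=list(config.long_covariates),
        baseline_names=baseline_names,
    )
    ds.validate()
    build_survival_covariates(ds, config)
    return ds


def write_joint_dataset(dataset: JointDataset, long_path, surv_path) -> None:
    """Write the two CSV files (times converted back to original units)."""
    part = dataset.partition
    long_rows = []
    surv_rows = []
    for s in dataset.subjects:
        for j in range(s.n_obs):
            row = {"id": s.id, "time": part.to_original(s.times[j]), "y": s.y[j]}
            for k, name in enumerate(dataset.covariate_names_long):
                row[name] = s.x_long[j, k]
            long_rows.append(row)
        srow = {"id": s.id, "s_star": s.s_star, "delta": s.delta}
        srow.update(s.baseline)
        surv_rows.append(srow)
    cols_long = ["id", "time", "y"] + list(dataset.covariate_names_long)
    pd.DataFrame(long_rows, columns=cols_long).to_csv(long_path, index=False)
    pd.DataFrame(surv_rows).to_csv(surv_path, index=False)
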