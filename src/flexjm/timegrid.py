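"""Discrete time partition and the truncated linear spline basis.

Follow-up time is discretized into ``M`` contiguous intervals whose
boundaries double as the internal knots of a truncated linear spline
basis ``{1, t, (t - k_1)_+, ..., (t - k_{M-1})_+}``.  A coefficient
vector of length ``M + 1`` applied to this basis yields a continuous
piecewise-linear trajectory whose slope is constant within each
interval; the linear maps below extract the trajectory's intercept and
slope at the start of any interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimePartition",
    "BasisMatrix",
    "interval_index",
    "basis_row",
    "design_matrix",
    "intercept_map",
    "slope_map",
    "association_design",
    "ASSOCIATION_TAGS",
]

ASSOCIATION_TAGS = ("intercept_slope", "intercept_only", "slope_only")


@dataclass(frozen=True)
class TimePartition:
    """Partition of the scaled follow-up window ``[0, k_M]``.

    Parameters
    ----------
    boundaries : array-like
        Strictly increasing boundary times ``k_0 = 0, k_1, ..., k_M`` on
        the scaled axis.  The interior values are the spline knots.
    scale : float
        Original time units per scaled unit (used only by readers and
        writers; internal computation is on the scaled axis).
    """

    boundaries: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("boundaries must be a 1-d vector of length >= 2")
        if b[0] != 0.0:
            raise ValueError("first boundary must be 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "boundaries", b)

    @property
    def M(self) -> int:
        """Number of intervals."""
        return self.boundaries.size - 1

    @property
    def knots(self) -> np.ndarray:
        """Internal knots ``k_1, ..., k_{M-1}``."""
        return self.boundaries[1:-1]

    @property
    def horizon(self) -> float:
        """Right endpoint ``k_M`` of the follow-up window."""
        return float(self.boundaries[-1])

    def to_original(self, t):
        return np.asarray(t, dtype=float) * self.scale

    def from_original(self, t):
        return np.asarray(t, dtype=float) / self.scale

    @classmethod
    def from_original_boundaries(cls, boundaries, scale: float) -> "TimePartition":
        b = np.asarray(boundaries, dtype=float) / scale
        return cls(boundaries=b, scale=scale)


@dataclass(frozen=True)
class BasisMatrix:
    """Truncated linear basis evaluated at a vector of time points."""

    values: np.ndarray  # (n, M+1)
    times: np.ndarray  # (n,)


def interval_index(t, part: TimePartition):
    """Map scaled time(s) to the 1-based interval index.

    Intervals are left-open/right-closed ``(k_{r-1}, k_r]``; ``t = 0``
    belongs to interval 1.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > part.horizon):
        bad = t_arr[(t_arr < 0) | (t_arr > part.horizon)]
        raise ValueError(
            f"time(s) {np.atleast_1d(bad)} outside the follow-up window "
            f"[0, {part.horizon}]"
        )
    # side='left': t exactly at a boundary is assigned to the interval ending there
    idx = np.searchsorted(part.boundaries, t_arr, side="left")
    idx = np.maximum(idx, 1)
    if np.ndim(t) == 0:
        return int(idx)
    return idx.astype(int)


def basis_row(t: float, part: TimePartition) -> np.ndarray:
    """Evaluate ``(1, t, (t - k_1)_+, ..., (t - k_{M-1})_+)`` at one time."""
    if t < 0:
        raise ValueError(f"time {t} must be nonnegative")
    row = np.empty(part.M + 1)
    row[0] = 1.0
    row[1] = t
    row[2:] = np.maximum(t - part.knots, 0.0)
    return row


def design_matrix(times, part: TimePartition) -> BasisMatrix:
    """Stack :func:`basis_row` over a vector of times (input order kept)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be a 1-d vector")
    if np.any(t < 0):
        raise ValueError("all times must be nonnegative")
    vals = np.empty((t.size, part.M + 1))
    vals[:, 0] = 1.0
    vals[:, 1] = t
    vals[:, 2:] = np.maximum(t[:, None] - part.knots[None, :], 0.0)
    return BasisMatrix(values=vals, times=t)


def intercept_map(r: int, part: TimePartition) -> np.ndarray:
    """Linear map ``w`` with ``w @ c`` the spline value at ``k_{r-1}``.

    Equals the basis row at the interval's left endpoint, so applying it
    to population-plus-random coefficients gives the trajectory's
    intercept at the start of interval ``r``.
    """
    if not 1 <= r <= part.M:
        raise IndexError(f"interval index {r} outside 1..{part.M}")
    return basis_row(float(part.boundaries[r - 1]), part)


def slope_map(r: int, part: TimePartition) -> np.ndarray:
    """Linear map ``w`` with ``w @ c`` the spline slope inside interval ``r``.

    The truncated linear basis has unit slope in column 1 and in every
    truncated column whose knot lies before the interval, so the map is
    an indicator of columns ``1..r``.
    """
    if not 1 <= r <= part.M:
        raise IndexError(f"interval index {r} outside 1..{part.M}")
    w = np.zeros(part.M + 1)
    w[1 : r + 1] = 1.0
    return w


def association_design(r: int, part: TimePartition, parameterization: str = "intercept_slope") -> np.ndarray:
    """Rows mapping spline coefficients to the interval-``r`` association terms.

    For ``intercept_slope`` the product with ``beta + b`` is
    ``(m(k_{r-1}), m'(k_{r-1}))``.
    """
    if parameterization == "intercept_slope":
        return np.vstack([intercept_map(r, part), slope_map(r, part)])
    if parameterization == "intercept_only":
        return intercept_map(r, part)[None, :]
    if parameterization == "slope_only":
        return slope_map(r, part)[None, :]
    raise ValueError(
        f"unknown association parameterization {parameterization!r}; "
        f"expected one of {ASSOCIATION_TAGS}"
    )


def association_tensor(part: TimePartition, parameterization: str = "intercept_slope") -> np.ndarray:
    """All association designs stacked: shape ``(M, q, M+1)``."""
    return np.stack(
        [association_design(r, part, parameterization) for r in range(1, part.M + 1)]
    )
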