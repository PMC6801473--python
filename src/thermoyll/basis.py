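"""Spline basis families used throughout the model.

Two families are built from first principles with explicit knot-placement
rules:

* **B-splines** via the Cox–de Boor recursion on a clamped (padded) knot
  vector.  A quadratic (degree-2) B-spline is the exposure basis for daily
  mean temperature.
* **Natural cubic splines**: cubic B-splines with the second derivative
  constrained to zero at (and beyond) the boundary knots, so the tails are
  linear.  Used for the long-term time trend, relative humidity, pollutant
  concentrations and the lag dimension of the temperature cross-basis.

Knot placement is *equally spaced over the covariate range* (not at
quantiles); for the lag dimension the spacing is applied on a log scale by
the caller.  Degrees of freedom follow the convention

    natural cubic:  df = n_interior_knots + 1  (+1 with intercept)
    B-spline:       df = n_interior_knots + degree  (+1 with intercept)

Values outside the boundary knots are clamped (B-splines, with a warning)
or extended linearly (natural splines, their defining property).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "BasisError",
    "basis_matrix",
    "bspline_basis",
    "natural_cubic_basis",
    "linear_strata_basis",
    "time_trend_basis",
]

_FAMILIES = ("natural_cubic", "bspline", "linear_strata")


class BasisError(ValueError):
    """Invalid basis specification or evaluation request."""


@dataclass(frozen=True)
class BasisSpec:
    """Declarative description of one spline basis.

    Either ``df`` or ``interior_knots`` must be given; with ``df`` alone the
    interior knots are placed at equally spaced values strictly inside the
    boundary knots (which default to the data range on first evaluation).
    """

    family: str
    degree: int = 3
    interior_knots: tuple[float, ...] | None = None
    boundary_knots: tuple[float, float] | None = None
    df: int | None = None
    intercept: bool = False

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise BasisError(f"unknown basis family {self.family!r}")
        if self.family == "bspline" and self.degree < 1:
            raise BasisError("bspline degree must be >= 1")
        if self.interior_knots is not None:
            k = np.asarray(self.interior_knots, dtype=float)
            if k.size > 1 and not np.all(np.diff(k) > 0):
                raise BasisError("interior knots must be strictly increasing")
        if self.boundary_knots is not None:
            a, b = self.boundary_knots
            if not (np.isfinite(a) and np.isfinite(b) and a < b):
                raise BasisError("boundary knots must be finite with low < high")
        if self.interior_knots is None and self.df is None and self.family != "linear_strata":
            raise BasisError("either df or interior_knots must be specified")

    @property
    def n_columns(self) -> int:
        """Number of basis columns once knots are resolved."""
        if self.family == "linear_strata":
            k = self.interior_knots or (0.0, 1.0)
            return len(k)
        if self.interior_knots is None:
            if self.df is None:
                raise BasisError("unresolved spec: no df and no knots")
            return self.df
        k = len(self.interior_knots)
        if self.family == "natural_cubic":
            return k + 1 + (1 if self.intercept else 0)
        return k + self.degree + (1 if self.intercept else 0)


@dataclass(frozen=True)
class BasisMatrix:
    """Evaluated basis: rows = observations, columns = basis functions."""

    values: np.ndarray
    spec: BasisSpec

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _n_interior_from_df(spec: BasisSpec) -> int:
    df = spec.df
    if df is None:
        raise BasisError("spec has neither df nor interior_knots")
    k = df - (1 if spec.intercept else 0)
    k -= 1 if spec.family == "natural_cubic" else spec.degree
    if k < 0:
        raise BasisError(
            f"df={df} too small for family {spec.family!r} "
            f"(degree {spec.degree}, intercept={spec.intercept})"
        )
    return k


def resolve_spec(spec: BasisSpec, x: np.ndarray) -> BasisSpec:
    """Fill in boundary knots (data range) and equally spaced interior knots."""
    boundary = spec.boundary_knots
    if boundary is None:
        lo, hi = float(np.min(x)), float(np.max(x))
        if lo == hi:
            # degenerate constant covariate: widen symmetrically
            lo, hi = lo - 0.5, hi + 0.5
        boundary = (lo, hi)
    interior = spec.interior_knots
    if interior is None and spec.family != "linear_strata":
        k = _n_interior_from_df(spec)
        interior = tuple(np.linspace(boundary[0], boundary[1], k + 2)[1:-1])
    return replace(spec, boundary_knots=boundary, interior_knots=interior)


# ---------------------------------------------------------------------------
# Cox–de Boor machinery


def _full_knot_vector(interior: Sequence[float], boundary: tuple[float, float],
                      degree: int) -> np.ndarray:
    a, b = boundary
    return np.concatenate([np.full(degree + 1, a), np.asarray(interior, float),
                           np.full(degree + 1, b)])


def _cox_de_boor(x: np.ndarray, t: np.ndarray, degree: int) -> np.ndarray:
    """All degree-`degree` B-spline basis functions on knot vector `t` at `x`.

    Half-open-interval convention, except that the right boundary knot is
    attached to the last non-empty span so the basis sums to one on the
    closed support interval.
    """
    m = len(t) - 1
    B = np.zeros((x.size, m))
    for i in range(m):
        if t[i] < t[i + 1]:
            B[:, i] = (x >= t[i]) & (x < t[i + 1])
    at_right = x == t[-1]
    if np.any(at_right):
        last = max(i for i in range(m) if t[i] < t[i + 1])
        B[at_right, :] = 0.0
        B[at_right, last] = 1.0
    for d in range(1, degree + 1):
        nb = m - d
        Bn = np.zeros((x.size, nb))
        for i in range(nb):
            left = t[i + d] - t[i]
            if left > 0:
                Bn[:, i] += (x - t[i]) / left * B[:, i]
            right = t[i + d + 1] - t[i + 1]
            if right > 0:
                Bn[:, i] += (t[i + d + 1] - x) / right * B[:, i + 1]
        B = Bn
    return B


def _bspline_design(x: np.ndarray, t: np.ndarray, degree: int,
                    deriv: int = 0) -> np.ndarray:
    """Design matrix of the B-spline basis or one of its derivatives.

    The `deriv`-th derivative of a degree-d basis function is a signed,
    knot-difference-scaled combination of two degree-(d−1) functions; the
    recursion bottoms out at the plain Cox–de Boor evaluation.
    """
    if deriv == 0:
        return _cox_de_boor(x, t, degree)
    if deriv > degree:
        return np.zeros((x.size, len(t) - degree - 1))
    lower = _bspline_design(x, t, degree - 1, deriv - 1)
    n = len(t) - degree - 1
    D = np.zeros((x.size, n))
    for i in range(n):
        left = t[i + degree] - t[i]
        if left > 0:
            D[:, i] += degree / left * lower[:, i]
        right = t[i + degree + 1] - t[i + 1]
        if right > 0:
            D[:, i] -= degree / right * lower[:, i + 1]
    return D


def _clamp(x: np.ndarray, boundary: tuple[float, float], warn: bool) -> np.ndarray:
    a, b = boundary
    out = (x < a) | (x > b)
    if np.any(out):
        if warn:
            warnings.warn(
                f"{int(out.sum())} value(s) outside boundary knots [{a}, {b}] "
                "clamped before basis evaluation", stacklevel=3)
        return np.clip(x, a, b)
    return x


# ---------------------------------------------------------------------------
# Public basis constructors


def bspline_basis(x, spec: BasisSpec) -> BasisMatrix:
    """B-spline basis by Cox–de Boor recursion on a clamped knot vector.

    Out-of-range values are clamped to the boundary knots with a warning.
    The intercept-inclusive basis is a partition of unity on the support.
    """
    if spec.family != "bspline":
        raise BasisError(f"expected bspline spec, got {spec.family!r}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    spec = resolve_spec(spec, x)
    t = _full_knot_vector(spec.interior_knots, spec.boundary_knots, spec.degree)
    xc = _clamp(x, spec.boundary_knots, warn=True)
    B = _bspline_design(xc, t, spec.degree)
    if not spec.intercept:
        B = B[:, 1:]
    return BasisMatrix(B, spec)


def _natural_transform(spec: BasisSpec) -> tuple[np.ndarray, np.ndarray]:
    """Knot vector and coefficient-space projection enforcing linear tails.

    The natural space is the null space of the two boundary second-derivative
    constraints on the cubic B-spline coefficients; without intercept the
    constant function's coefficient direction (the all-ones vector, by
    partition of unity) is additionally projected out.
    """
    t = _full_knot_vector(spec.interior_knots, spec.boundary_knots, 3)
    a, b = spec.boundary_knots
    C = _bspline_design(np.array([a, b]), t, 3, deriv=2)
    if not spec.intercept:
        C = np.vstack([C, np.ones((1, C.shape[1]))])
    Z = null_space(C)
    return t, Z


def natural_cubic_basis(x, spec: BasisSpec) -> BasisMatrix:
    """Natural cubic spline basis: cubic inside, linear beyond the boundary.

    Values beyond the boundary knots are extended linearly (first-order
    Taylor expansion from the boundary), which is exact for a natural spline.
    """
    if spec.family != "natural_cubic":
        raise BasisError(f"expected natural_cubic spec, got {spec.family!r}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    spec = resolve_spec(spec, x)
    t, Z = _natural_transform(spec)
    a, b = spec.boundary_knots
    xin = np.clip(x, a, b)
    N = _bspline_design(xin, t, 3) @ Z
    for bound, mask in ((a, x < a), (b, x > b)):
        if np.any(mask):
            pt = np.array([bound])
            val = _bspline_design(pt, t, 3) @ Z
            der = _bspline_design(pt, t, 3, deriv=1) @ Z
            N[mask] = val + (x[mask, None] - bound) * der
    return BasisMatrix(N, spec)


def linear_strata_basis(x, spec: BasisSpec) -> BasisMatrix:
    """Indicator basis: one column per stratum value (exact match).

    Used for the pollutant lag dimension — unconstrained strata at lag 0 and
    lag 1.
    """
    if spec.family != "linear_strata":
        raise BasisError(f"expected linear_strata spec, got {spec.family!r}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    strata = spec.interior_knots or (0.0, 1.0)
    B = np.column_stack([(x == s).astype(float) for s in strata])
    return BasisMatrix(B, replace(spec, interior_knots=tuple(strata)))


def basis_matrix(x, spec: BasisSpec) -> BasisMatrix:
    """Evaluate any basis family from its spec."""
    if spec.family == "bspline":
        return bspline_basis(x, spec)
    if spec.family == "natural_cubic":
        return natural_cubic_basis(x, spec)
    return linear_strata_basis(x, spec)


def time_trend_basis(dates, df_per_year: int) -> BasisMatrix:
    """Natural cubic spline over the day index controlling the long-term trend.

    Total df = df_per_year × whole years in the series (7 df/year over a
    four-year series gives 28 columns), with knots equally spaced over the
    index range.
    """
    if df_per_year < 1:
        raise BasisError("df_per_year must be >= 1")
    n = len(dates)
    n_years = max(1, int(round(n / 365.25)))
    df = df_per_year * n_years
    idx = np.arange(n, dtype=float)
    spec = BasisSpec(family="natural_cubic", df=df, intercept=False)
    return natural_cubic_basis(idx, spec)
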