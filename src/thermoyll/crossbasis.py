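"""Cross-basis construction for distributed-lag non-linear models.

A cross-basis is the tensor product of a basis over exposure values
(R_1..R_J) and a basis over lag days (C_1..C_K).  Its design entry for day
t and column (j, k) is

    CB[t, j*K + k] = sum_{l=0..L} R_j(x_{t-l}) * C_k(l)

so that a coefficient vector on the cross-basis encodes a full
exposure–lag–response surface.  Rows without a complete lag history (the
first L days) are flagged invalid and dropped at fit time.

Defaults follow the temperature–YLL model: the temperature exposure basis
is a quadratic B-spline with knots equally spaced across the temperature
range; the lag basis is a natural cubic spline in log(lag+1) with knots
equally spaced on that log scale, over lags 0–30.  Pollutants use a natural
cubic exposure basis with a simple unconstrained lag 0–1 stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .basis import BasisError, BasisSpec, basis_matrix, resolve_spec

__all__ = [
    "CrossBasisSpec",
    "CrossBasis",
    "build_crossbasis",
    "temperature_crossbasis_spec",
    "pollutant_crossbasis_spec",
]


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure basis × lag basis × maximum lag.

    ``lag_transform`` maps lag day l to the scale the lag basis lives on:
    ``"log1p"`` (log(l+1), so lag 0 is finite) or ``"identity"``.
    """

    var_spec: BasisSpec
    lag_spec: BasisSpec
    max_lag: int
    lag_transform: str = "identity"

    def __post_init__(self):
        if self.max_lag < 0:
            raise BasisError("max_lag must be >= 0")
        if self.lag_transform not in ("identity", "log1p"):
            raise BasisError(f"unknown lag_transform {self.lag_transform!r}")

    def lag_values(self) -> np.ndarray:
        lags = np.arange(self.max_lag + 1, dtype=float)
        return np.log1p(lags) if self.lag_transform == "log1p" else lags


def temperature_crossbasis_spec(max_lag: int = 30, var_df: int = 5,
                                lag_df: int = 5,
                                boundary_knots: tuple[float, float] | None = None,
                                ) -> CrossBasisSpec:
    """Default temperature cross-basis: quadratic B-spline exposure basis
    (equally spaced knots) × natural cubic lag basis with intercept, knots
    equally spaced in log(lag+1)."""
    var = BasisSpec(family="bspline", degree=2, df=var_df,
                    boundary_knots=boundary_knots, intercept=False)
    lag = BasisSpec(family="natural_cubic", df=lag_df, intercept=True)
    return CrossBasisSpec(var_spec=var, lag_spec=lag, max_lag=max_lag,
                          lag_transform="log1p")


def pollutant_crossbasis_spec(var_df: int = 3, max_lag: int = 1,
                              boundary_knots: tuple[float, float] | None = None,
                              ) -> CrossBasisSpec:
    """Default pollutant cross-basis: natural cubic in concentration ×
    unconstrained lag strata over lags 0..max_lag."""
    var = BasisSpec(family="natural_cubic", df=var_df,
                    boundary_knots=boundary_knots, intercept=False)
    lag = BasisSpec(family="linear_strata",
                    interior_knots=tuple(float(l) for l in range(max_lag + 1)))
    return CrossBasisSpec(var_spec=var, lag_spec=lag, max_lag=max_lag)


@dataclass(frozen=True)
class CrossBasis:
    """Lag-expanded design block plus everything needed to rebuild contrast
    vectors at prediction time (the resolved spec with concrete knots)."""

    matrix: np.ndarray
    spec: CrossBasisSpec
    valid_rows: np.ndarray  # bool mask, False for rows missing lag history

    @property
    def var_df(self) -> int:
        return self.spec.var_spec.n_columns

    @property
    def lag_df(self) -> int:
        return self.spec.lag_spec.n_columns

    def var_design(self, values) -> np.ndarray:
        """Exposure basis rows at arbitrary values (clamped at the boundary)."""
        return basis_matrix(values, self.spec.var_spec).values

    def lag_design(self) -> np.ndarray:
        """Lag basis evaluated at lags 0..max_lag: shape (L+1, lag_df)."""
        return basis_matrix(self.spec.lag_values(), self.spec.lag_spec).values


def build_crossbasis(series, spec: CrossBasisSpec) -> CrossBasis:
    """Build the cross-basis matrix for one exposure series.

    Exposure-basis knots left unresolved in the spec are fixed here from the
    observed series range, and the resolved spec is stored on the result so
    predictions reuse identical bases.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise BasisError("exposure series must be one-dimensional")
    n = x.size
    L = spec.max_lag
    if n <= L:
        raise BasisError(f"series length {n} must exceed max_lag {L}")

    var_spec = resolve_spec(spec.var_spec, x)
    lag_vals = spec.lag_values()
    lag_spec = spec.lag_spec
    if lag_spec.family != "linear_strata":
        lag_spec = resolve_spec(lag_spec, lag_vals)
    rspec = replace(spec, var_spec=var_spec, lag_spec=lag_spec)

    R = basis_matrix(x, var_spec).values            # (n, J)
    C = basis_matrix(lag_vals, lag_spec).values     # (L+1, K)
    J, K = R.shape[1], C.shape[1]

    CB = np.zeros((n, J * K))
    for l in range(L + 1):
        Rl = np.empty_like(R)
        Rl[l:] = R[: n - l] if l else R
        Rl[:l] = 0.0  # incomplete history; rows masked below
        CB += np.einsum("tj,k->tjk", Rl, C[l]).reshape(n, J * K)
    valid = np.ones(n, dtype=bool)
    valid[:L] = False
    return CrossBasis(matrix=CB, spec=rspec, valid_rows=valid)
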