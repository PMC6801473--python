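"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — literal recursions, truncated-power
algebra, per-record loops — and shares no code with the implementation
under test.
"""

import numpy as np


def naive_bspline(x: float, i: int, degree: int, t: np.ndarray) -> float:
    """Textbook recursive Cox–de Boor evaluation of one basis function."""
    if degree == 0:
        if t[i] <= x < t[i + 1]:
            return 1.0
        # close the last non-empty span on the right
        if x == t[-1] and t[i] < t[i + 1] and t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    out = 0.0
    if t[i + degree] > t[i]:
        out += (x - t[i]) / (t[i + degree] - t[i]) \
            * naive_bspline(x, i, degree - 1, t)
    if t[i + degree + 1] > t[i + 1]:
        out += (t[i + degree + 1] - x) / (t[i + degree + 1] - t[i + 1]) \
            * naive_bspline(x, i + 1, degree - 1, t)
    return out


def naive_bspline_design(x: np.ndarray, interior, boundary, degree: int):
    a, b = boundary
    t = np.r_[[a] * (degree + 1), interior, [b] * (degree + 1)]
    n_basis = len(t) - degree - 1
    return np.array([[naive_bspline(float(xi), i, degree, t)
                      for i in range(n_basis)] for xi in x])


def truncated_power_natural_design(x: np.ndarray, interior, boundary):
    """Natural cubic spline space via the reduced truncated-power basis:
    {1, x, d_k(x) - d_{K-1}(x)} with d_k(x) = [(x-k)+^3 - (x-kK)+^3] / (kK-k)
    (boundary knots included as knots), which spans the same space.
    """
    knots = np.r_[boundary[0], interior, boundary[1]]
    K = len(knots)

    def d(k, xs):
        return (np.maximum(xs - knots[k], 0) ** 3
                - np.maximum(xs - knots[K - 1], 0) ** 3) / (knots[K - 1] - knots[k])

    cols = [np.ones_like(x), x]
    for k in range(K - 2):
        cols.append(d(k, x) - d(K - 2, x))
    return np.column_stack(cols)


def naive_crossbasis(series: np.ndarray, var_design, lag_design,
                     max_lag: int) -> np.ndarray:
    """Double loop over (day, lag): CB[t, j*K+k] = sum_l R_j(x_{t-l}) C_k(l).

    Lags reaching before the series start contribute zero (rows are masked
    by the caller).
    """
    n = len(series)
    R = var_design(series)
    C = lag_design(np.arange(max_lag + 1))
    J, K = R.shape[1], C.shape[1]
    CB = np.zeros((n, J * K))
    for t in range(n):
        for l in range(max_lag + 1):
            if t - l < 0:
                continue
            for j in range(J):
                for k in range(K):
                    CB[t, j * K + k] += R[t - l, j] * C[l, k]
    return CB


def per_record_daily_yll(records, lookup, calendar) -> dict:
    """Naive all-cause daily YLL: a dict date -> sum of per-record values."""
    out = {d: 0.0 for d in calendar}
    for r in records:
        out[r.death_date] += lookup(r)
    return out
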