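"""Gaussian time-series regression of daily YLL on a temperature cross-basis.

The model, on day t of the series,

    E(YLL_t) = crossbasis(temperature, lags 0..30)
             + crossbasis(pollutant_p, lags 0..1)   for each pollutant p
             + NS(time, df_per_year × years) + NS(humidity, 3)
             + day-of-week + holiday + intercept

is fitted by ordinary least squares (daily YLL is approximately Gaussian,
so the family is Gaussian with identity link).  Rows without a complete
temperature lag history (the first max_lag days) are dropped, never
imputed.  The coefficient covariance is s²(XᵀX)⁻¹ with s² = RSS/(n−p).

Follows the statsmodels idiom: ``TemperatureYLLModel(daily).fit()`` returns
a ``TemperatureYLLResults`` carrying estimates, covariance and the resolved
cross-basis specs, from which cold/heat contrasts, lag curves, summaries
and plots are derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import effects as _effects
from .basis import BasisError, BasisSpec, natural_cubic_basis, time_trend_basis
from .crossbasis import (CrossBasis, CrossBasisSpec, build_crossbasis,
                         pollutant_crossbasis_spec, temperature_crossbasis_spec)
from .effects import ContrastDefinition, CurveSummary, EffectEstimate

__all__ = [
    "ModelConfig",
    "DesignInfo",
    "build_design",
    "fit_gaussian",
    "TemperatureYLLModel",
    "TemperatureYLLResults",
]

POLLUTANTS = ("pm10", "no2", "so2", "co", "o3")


class ModelError(ValueError):
    """Invalid model configuration or data."""


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the YLL regression.

    The temperature exposure basis is a quadratic B-spline with ``temp_var_df``
    columns (equally spaced knots over the observed range); the lag basis a
    natural cubic spline with intercept in log(lag+1) with ``temp_lag_df``
    columns.  Pollutant cross-bases pair a natural cubic concentration basis
    with unconstrained lag 0–1 strata.
    """

    response: str = "all"
    max_lag: int = 30
    temp_var_df: int = 5
    temp_lag_df: int = 5
    temp_boundary_knots: tuple[float, float] | None = None
    time_df_per_year: int = 7
    humidity_df: int = 3
    pollutants: tuple[str, ...] = POLLUTANTS
    pollutant_var_df: int = 3
    pollutant_max_lag: int = 1

    def __post_init__(self):
        for name, lo in (("max_lag", 0), ("temp_var_df", 3), ("temp_lag_df", 2),
                         ("time_df_per_year", 1), ("humidity_df", 1),
                         ("pollutant_var_df", 1), ("pollutant_max_lag", 0)):
            if getattr(self, name) < lo:
                raise ModelError(f"{name} must be >= {lo}")

    def replace(self, **kw) -> "ModelConfig":
        kw = {k: (tuple(v) if k == "pollutants" else v) for k, v in kw.items()}
        return replace(self, **kw)


@dataclass
class DesignInfo:
    """Design matrix with named column blocks and the row mask applied."""

    matrix: np.ndarray
    layout: dict[str, slice]
    valid_rows: np.ndarray
    temp_crossbasis: CrossBasis
    pollutant_crossbases: dict[str, CrossBasis]
    column_names: list[str]


def _dow_block(dates: pd.Series) -> tuple[np.ndarray, list[str]]:
    # 6 indicators, Sunday (weekday 6) as reference; estimates of the
    # temperature contrasts are invariant to the reference choice
    wd = pd.DatetimeIndex(dates).weekday.to_numpy()
    cols = [(wd == d).astype(float) for d in range(6)]
    return np.column_stack(cols), [f"dow_{d}" for d in range(6)]


def build_design(daily: pd.DataFrame, config: ModelConfig) -> DesignInfo:
    """Assemble the full design matrix from a validated daily series."""
    required = ["date", "temperature", "humidity"] + list(config.pollutants)
    missing = [c for c in required if c not in daily.columns]
    if missing:
        raise ModelError(f"daily series missing columns: {missing}")
    for col in required[1:]:
        bad = daily.index[daily[col].isna()]
        if len(bad):
            dates = pd.DatetimeIndex(daily["date"]).strftime("%Y-%m-%d")
            raise ModelError(
                f"missing values in {col!r} on dates "
                f"{list(dates[bad][:5])}{'...' if len(bad) > 5 else ''}")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    layout: dict[str, slice] = {}

    def add(name: str, mat: np.ndarray, colnames: list[str]):
        start = sum(b.shape[1] for b in blocks)
        blocks.append(mat)
        names.extend(colnames)
        layout[name] = slice(start, start + mat.shape[1])

    tspec = temperature_crossbasis_spec(max_lag=config.max_lag,
                                        var_df=config.temp_var_df,
                                        lag_df=config.temp_lag_df,
                                        boundary_knots=config.temp_boundary_knots)
    temp_cb = build_crossbasis(daily["temperature"].to_numpy(), tspec)
    add("temperature", temp_cb.matrix,
        [f"temp_cb_{i}" for i in range(temp_cb.matrix.shape[1])])

    poll_cbs: dict[str, CrossBasis] = {}
    for p in config.pollutants:
        pspec = pollutant_crossbasis_spec(var_df=config.pollutant_var_df,
                                          max_lag=config.pollutant_max_lag)
        cb = build_crossbasis(daily[p].to_numpy(), pspec)
        poll_cbs[p] = cb
        add(p, cb.matrix, [f"{p}_cb_{i}" for i in range(cb.matrix.shape[1])])

    trend = time_trend_basis(daily["date"], config.time_df_per_year)
    add("time", trend.values, [f"time_{i}" for i in range(trend.values.shape[1])])

    hum = natural_cubic_basis(
        daily["humidity"].to_numpy(),
        BasisSpec(family="natural_cubic", df=config.humidity_df, intercept=False))
    add("humidity", hum.values, [f"hum_{i}" for i in range(hum.values.shape[1])])

    dow, dow_names = _dow_block(daily["date"])
    add("dow", dow, dow_names)

    holiday = (daily["holiday"].to_numpy(dtype=float)[:, None]
               if "holiday" in daily.columns
               else np.zeros((len(daily), 1)))
    if holiday.any():
        add("holiday", holiday, ["holiday"])

    add("intercept", np.ones((len(daily), 1)), ["intercept"])

    valid = temp_cb.valid_rows.copy()
    for cb in poll_cbs.values():
        valid &= cb.valid_rows
    X = np.hstack(blocks)
    return DesignInfo(matrix=X, layout=layout, valid_rows=valid,
                      temp_crossbasis=temp_cb, pollutant_crossbases=poll_cbs,
                      column_names=names)


@dataclass
class FitResult:
    """OLS estimates for the full design: coefficients, covariance,
    residual SD, rows used, and the named column layout."""

    params: np.ndarray
    cov_params: np.ndarray
    resid_sd: float
    n_used: int
    layout: dict[str, slice]
    column_names: list[str]


def fit_gaussian(design: np.ndarray, response: np.ndarray,
                 layout: dict[str, slice] | None = None,
                 column_names: list[str] | None = None) -> FitResult:
    """Ordinary least squares with exact covariance s²(XᵀX)⁻¹.

    Raises on rank deficiency, identifying the collinear block when a
    layout is supplied.
    """
    X = np.asarray(design, float)
    y = np.asarray(response, float)
    n, p = X.shape
    if n <= p:
        raise ModelError(f"n={n} rows is not greater than p={p} columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        culprit = ""
        if layout:
            for name, sl in layout.items():
                sub = X[:, sl]
                if np.linalg.matrix_rank(sub) < sub.shape[1]:
                    culprit = f" (block {name!r} is rank-deficient)"
                    break
            else:
                culprit = " (collinearity across blocks)"
        raise ModelError(f"design matrix rank {rank} < {p} columns{culprit}")
    res = sm.OLS(y, X).fit()
    return FitResult(params=res.params, cov_params=res.cov_params(),
                     resid_sd=float(np.sqrt(res.scale)), n_used=n,
                     layout=layout or {"all": slice(0, p)},
                     column_names=column_names or [f"x{i}" for i in range(p)])


class TemperatureYLLModel:
    """Distributed-lag non-linear Gaussian model of daily YLL on temperature.

    Parameters
    ----------
    daily : DataFrame
        Validated daily series with ``date``, ``temperature``, ``humidity``,
        pollutant columns, optional ``holiday`` flag, and one or more YLL
        response columns.
    config : ModelConfig, optional
        Basis dimensions, maximum lag, confounder df and pollutant set.

    Examples
    --------
    >>> res = TemperatureYLLModel(daily, ModelConfig(response="all")).fit()
    >>> res.cold_effect()                   # cumulative lag 0-30, 25th->1st
    >>> res.summary_table("cold")           # significant duration etc.
    """

    def __init__(self, daily: pd.DataFrame, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.daily = daily.reset_index(drop=True)
        if self.config.response not in self.daily.columns:
            raise ModelError(
                f"response column {self.config.response!r} not in daily series")
        self.design = build_design(self.daily, self.config)
        self.endog = self.daily[self.config.response].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, daily: pd.DataFrame, response: str = "all",
                       **config_kwargs) -> "TemperatureYLLModel":
        if "pollutants" not in config_kwargs:
            present = tuple(p for p in POLLUTANTS if p in daily.columns)
            config_kwargs["pollutants"] = present
        return cls(daily, ModelConfig(response=response, **config_kwargs))

    def fit(self) -> "TemperatureYLLResults":
        mask = self.design.valid_rows
        fr = fit_gaussian(self.design.matrix[mask], self.endog[mask],
                          layout=self.design.layout,
                          column_names=self.design.column_names)
        return TemperatureYLLResults(self, fr)


class TemperatureYLLResults:
    """Fit results: coefficients, covariance and effect estimation.

    Cold/heat contrasts, lag curves and cumulative curves are delta-method
    linear functionals of the temperature cross-basis block.
    """

    def __init__(self, model: TemperatureYLLModel, fit: FitResult):
        self.model = model
        self.params = fit.params
        self.cov_params = fit.cov_params
        self.resid_sd = fit.resid_sd
        self.n_used = fit.n_used
        self.layout = fit.layout
        self.column_names = fit.column_names
        self.temp_crossbasis = model.design.temp_crossbasis
        self.contrasts = ContrastDefinition()

    # -- contrasts ---------------------------------------------------------

    def percentile_contrasts(self) -> dict[str, tuple[float, float]]:
        """(ref, target) temperatures for the cold and heat contrasts,
        computed on the full observed temperature series."""
        return self.contrasts.resolve(self.model.daily["temperature"].to_numpy())

    def _pair(self, contrast: str) -> tuple[float, float]:
        ref, target = self.percentile_contrasts()[contrast]
        return target, ref

    def lag_effect(self, target: float, ref: float, lag: int) -> EffectEstimate:
        return _effects.lag_effect(self, target, ref, lag)

    def cumulative_effect(self, target: float, ref: float,
                          lag_window=(0, None)) -> EffectEstimate:
        return _effects.cumulative_effect(self, target, ref, lag_window)

    def lag_curve(self, contrast: str = "cold") -> list[EffectEstimate]:
        return _effects.lag_curve(self, *self._pair(contrast))

    def cumulative_curve(self, contrast: str = "cold") -> list[EffectEstimate]:
        return _effects.cumulative_curve(self, *self._pair(contrast))

    def cold_effect(self, lag_window=(0, None)) -> EffectEstimate:
        return self.cumulative_effect(*self._pair("cold"), lag_window)

    def heat_effect(self, lag_window=(0, None)) -> EffectEstimate:
        return self.cumulative_effect(*self._pair("heat"), lag_window)

    def summary_table(self, contrast: str, cumulative: bool = False) -> CurveSummary:
        curve = (self.cumulative_curve(contrast) if cumulative
                 else self.lag_curve(contrast))
        return _effects.summarize_curve(curve, cumulative=cumulative)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        pc = self.percentile_contrasts()
        lines = [
            "Temperature-YLL distributed-lag model (Gaussian, identity link)",
            "=" * 64,
            f"response: {cfg.response}    days used: {self.n_used}"
            f"    residual SD: {self.resid_sd:.2f} years",
            f"max lag: {cfg.max_lag}    temp basis: quadratic B-spline"
            f" df={cfg.temp_var_df}    lag basis: ns(log(lag+1)) df={cfg.temp_lag_df}",
            f"time trend: {cfg.time_df_per_year} df/year    humidity:"
            f" {cfg.humidity_df} df    pollutants: "
            + (", ".join(cfg.pollutants) if cfg.pollutants else "none"),
            f"cold contrast: {pc['cold'][0]:.2f} -> {pc['cold'][1]:.2f} C"
            f" (25th -> 1st pctl)",
            f"heat contrast: {pc['heat'][0]:.2f} -> {pc['heat'][1]:.2f} C"
            f" (75th -> 99th pctl)",
            "-" * 64,
        ]
        for name in ("cold", "heat"):
            eff = self.cumulative_effect(*self._pair(name))
            lines.append(
                f"{name} cumulative YLL (lag 0-{cfg.max_lag}): "
                f"{eff.estimate:.2f} ({eff.ci_low:.2f}, {eff.ci_high:.2f})"
                f"{' *' if eff.significant else ''}")
            row = self.summary_table(name)
            lines.append(f"  single-day significant duration: "
                         f"{row.significant_duration}; strongest: "
                         f"{row.strongest_lag}; highest YLL: {row.highest_yll}")
        return "\n".join(lines)

    def plot_lag_curve(self, contrast: str = "cold", cumulative: bool = False,
                       ax=None):
        """Lag curve with 95% band: bold effect line, shaded CI."""
        import matplotlib.pyplot as plt

        curve = (self.cumulative_curve(contrast) if cumulative
                 else self.lag_curve(contrast))
        lags = np.arange(len(curve))
        est = [e.estimate for e in curve]
        lo = [e.ci_low for e in curve]
        hi = [e.ci_high for e in curve]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.fill_between(lags, lo, hi, color="0.8")
        ax.plot(lags, est, color="k", lw=2)
        ax.axhline(0.0, color="0.4", lw=0.8, ls="--")
        ax.set_xlabel("lag (days)")
        ax.set_ylabel("YLL difference (years)")
        kind = "cumulative" if cumulative else "single-day"
        ax.set_title(f"{kind} {contrast} effect")
        return ax

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialize coefficients, covariance, layout and the resolved
        temperature cross-basis spec."""
        cb = self.temp_crossbasis
        payload = {
            "params": self.params.tolist(),
            "cov_params": self.cov_params.tolist(),
            "resid_sd": self.resid_sd,
            "n_used": self.n_used,
            "layout": {k: [v.start, v.stop] for k, v in self.layout.items()},
            "column_names": self.column_names,
            "config": asdict(self.model.config),
            "temp_crossbasis": {
                "max_lag": cb.spec.max_lag,
                "lag_transform": cb.spec.lag_transform,
                "var_spec": asdict(cb.spec.var_spec),
                "lag_spec": asdict(cb.spec.lag_spec),
            },
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
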