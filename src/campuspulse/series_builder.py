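"""Monthly-series preparation: normalization, residualization, lag scans.

The consultation and expression series both carry academic-calendar trend
and seasonality, so raw cross-correlations would be dominated by the
shared calendar.  The pipeline therefore (1) normalizes consultations to
a percent-of-enrollment rate, (2) removes a moving-window trend and a
period-12 seasonal component from every series, verifying stationarity of
the residuals with an augmented Dickey-Fuller test, and (3) regresses the
consultation residuals on lagged expression residuals while controlling
for both series' previous-month values, reporting a standardized
coefficient ``e`` per lag.

Series are represented as :class:`pandas.Series` with a monthly
``PeriodIndex``; the helpers here are the only place gap policy and edge
policy live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tsa.stattools import adfuller


@dataclass(frozen=True)
class StationarityReport:
    test_statistic: float
    p_value: float
    stationary: bool
    degenerate: bool = False


@dataclass(frozen=True)
class DecompositionResult:
    """Additive decomposition: trend + seasonal + residual == original."""

    trend: pd.Series
    seasonal: pd.Series
    residual: pd.Series
    window: int


@dataclass(frozen=True)
class LagCorrelationResult:
    """Standardized slope of the lagged expression residual in the
    controlled regression, with its two-sided p-value."""

    outcome: str
    lag: int
    e: float
    p_value: float
    n_obs: int


def normalize_consultations(
    visits: pd.Series, enrollment: pd.Series | int
) -> pd.Series:
    """Consultation rate as percent of enrolled: 100 * visits / enrollment."""
    visits = visits.astype(float)
    if np.any(visits.to_numpy() < 0):
        raise ValueError("negative visit counts")
    if np.isscalar(enrollment):
        enrollment = pd.Series(float(enrollment), index=visits.index)
    enrollment = enrollment.astype(float)
    if np.any(enrollment.to_numpy() <= 0):
        raise ValueError("enrollment must be positive")
    rate = 100.0 * visits / enrollment
    rate.name = "rate_percent"
    return rate


def fill_missing(series: pd.Series) -> pd.Series:
    """Linear interpolation over missing months (gap policy), with warning."""
    if series.isna().any():
        warnings.warn(
            f"interpolating {int(series.isna().sum())} missing month(s)"
        )
        series = series.interpolate(limit_direction="both")
    return series


def adf_test(series: pd.Series, alpha: float = 0.05) -> StationarityReport:
    """Augmented Dickey-Fuller unit-root test; stationary iff p < alpha.

    Lag order selected by AIC up to floor((n-1)^(1/3)).  A constant series
    is reported non-stationary with ``degenerate=True`` rather than raised.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 24:
        raise ValueError("need at least 24 months for the stationarity test")
    if np.isnan(x).any():
        raise ValueError("series contains missing values; fill gaps first")
    if np.ptp(x) == 0:
        return StationarityReport(np.nan, 1.0, False, degenerate=True)
    maxlag = int(np.floor((len(x) - 1) ** (1.0 / 3.0)))
    stat, pval, *_ = adfuller(x, maxlag=maxlag, autolag="AIC")
    return StationarityReport(float(stat), float(pval), bool(pval < alpha))


def _centered_ma(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; even windows use the standard half-weight
    ends (a 2xW average) so the filter stays symmetric."""
    if window % 2 == 1:
        w = np.full(window, 1.0 / window)
        half = window // 2
    else:
        w = np.full(window + 1, 1.0 / window)
        w[0] = w[-1] = 0.5 / window
        half = window // 2
    valid = np.convolve(x, w, mode="valid")
    trend = np.full(len(x), np.nan)
    trend[half:half + len(valid)] = valid
    return trend


def decompose(series: pd.Series, window: int = 12) -> DecompositionResult:
    """Classical additive decomposition with a moving-average trend.

    trend: centered moving average of width ``window`` (edges padded with
    the nearest interior value); seasonal: per-calendar-month mean of the
    detrended series, re-centred to sum to zero over the 12 months;
    residual: the remainder.  The three parts sum to the input exactly.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    x = series.to_numpy(dtype=float)
    if len(x) < 2 * window:
        raise ValueError("series must be at least twice the window length")
    trend = _centered_ma(x, window)
    interior = ~np.isnan(trend)
    detrended = x - trend
    moy = np.asarray(series.index.month)
    seas_by_month = np.zeros(12)
    for m in range(1, 13):
        mask = (moy == m) & interior  # edge months would leak pad bias
        if mask.any():
            seas_by_month[m - 1] = detrended[mask].mean()
    seas_by_month -= seas_by_month.mean()
    seasonal = seas_by_month[moy - 1]
    # edge policy: extend the trend with the nearest interior estimate
    first, last = np.flatnonzero(interior)[[0, -1]]
    trend[:first] = trend[first]
    trend[last + 1:] = trend[last]
    residual = x - trend - seasonal
    idx = series.index
    return DecompositionResult(
        trend=pd.Series(trend, idx, name="trend"),
        seasonal=pd.Series(seasonal, idx, name="seasonal"),
        residual=pd.Series(residual, idx, name="residual"),
        window=window,
    )


def residualize(
    series: pd.Series, window: int = 12, alpha: float = 0.05
) -> tuple[pd.Series, StationarityReport]:
    """Trend/seasonality-removed residual plus its stationarity report.

    Warns (but does not fail) if the residual still fails the
    Dickey-Fuller gate at ``alpha``.
    """
    series = fill_missing(series)
    resid = decompose(series, window=window).residual
    report = adf_test(resid, alpha=alpha)
    if not report.stationary:
        warnings.warn(
            f"residual series still non-stationary (ADF p={report.p_value:.3f})"
        )
    return resid, report


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance regressor")
    return (x - x.mean()) / sd


def lagged_association(
    visits_resid: pd.Series,
    expr_resid: pd.Series,
    lag: int,
    controls: tuple[str, ...] = ("prev_visits", "prev_expr"),
    outcome: str = "",
) -> LagCorrelationResult:
    """Standardized coefficient of the expression residual at ``lag``.

    OLS of visits_t on expr_{t-lag}, optionally controlling for
    visits_{t-1} and expr_{t-1}; all variables standardized over the
    aligned span so ``e`` is comparable across outcomes.  When
    ``lag == 1`` the predictor coincides with the previous-month
    expression control, which is then dropped to avoid perfect
    collinearity.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    df = pd.DataFrame({
        "y": visits_resid,
        "x": expr_resid.shift(lag),
        "prev_visits": visits_resid.shift(1),
        "prev_expr": expr_resid.shift(1),
    })
    use = ["y", "x"] + [c for c in controls if not (c == "prev_expr" and lag == 1)]
    df = df[use].dropna()
    if len(df) < 12:
        raise ValueError("insufficient overlap after lag alignment")
    Z = {c: _standardize(df[c].to_numpy()) for c in df.columns}
    X = sm.add_constant(
        np.column_stack([Z[c] for c in df.columns if c != "y"])
    )
    fit = sm.OLS(Z["y"], X).fit()
    return LagCorrelationResult(
        outcome=outcome,
        lag=lag,
        e=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        n_obs=len(df),
    )


def scan_lags(
    visits_resid: pd.Series,
    expr_resid: pd.Series,
    max_lag: int = 6,
    controls: tuple[str, ...] = ("prev_visits", "prev_expr"),
    outcome: str = "",
) -> pd.DataFrame:
    """Lag scan 0..max_lag; one row per lag with e and p."""
    rows = [
        lagged_association(visits_resid, expr_resid, lag, controls, outcome)
        for lag in range(max_lag + 1)
    ]
    return pd.DataFrame(
        {"outcome": [r.outcome for r in rows],
         "lag": [r.lag for r in rows],
         "e": [r.e for r in rows],
         "p_value": [r.p_value for r in rows],
         "n_obs": [r.n_obs for r in rows]}
    )
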