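"""SARIMA forecasting of consultations, with and without social-media data.

Two models are compared under a common anchored k-fold cross-validation:

* **M0** -- SARIMA on the consultation-rate series alone (the baseline a
  health center could run today);
* **M1** -- the same SARIMA with monthly symptomatic-expression
  prevalences as exogenous regressors (by default depression, anxiety,
  stress and suicidal ideation).

The first 12 months are an anchor that stays in every training set; the
remaining months are partitioned into k contiguous blocks, each predicted
by a model fit on everything else.  Fold fitting masks the test block as
missing so the Kalman filter skips those observations while the rest of
the series, and the exogenous covariates, stay available (the covariates
are observed for test months: a nowcasting contract).  Pooled predictions
are scored by Pearson's r, MAE and SMAPE, compared against a permutation
null, and against each other with the dependent overlapping correlation
(Williams/Steiger) t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.statespace.sarimax import SARIMAX

DEFAULT_EXOG_OUTCOMES: tuple[str, ...] = (
    "depression",
    "anxiety",
    "stress",
    "suicidal_ideation",
)


def _default_grid() -> tuple[tuple[tuple[int, int, int], tuple[int, int, int, int]], ...]:
    grid = []
    for p in (0, 1):
        for d in (0, 1):
            for q in (0, 1):
                for P in (0, 1):
                    for D in (0, 1):
                        for Q in (0, 1):
                            grid.append(((p, d, q), (P, D, Q, 12)))
    return tuple(grid)


@dataclass(frozen=True)
class ForecastConfig:
    k: int = 10
    anchor: int = 12          # months always kept in training
    seasonal_period: int = 12
    #: fixed (order, seasonal_order); when None the grid is searched by AIC
    orders: tuple[tuple[int, int, int], tuple[int, int, int, int]] | None = None
    grid: tuple = field(default_factory=_default_grid)
    exog_outcomes: tuple[str, ...] = DEFAULT_EXOG_OUTCOMES
    #: months by which exogenous covariates are shifted back in time, so a
    #: post stream that leads consultations by L months aligns at exog_lag=L
    exog_lag: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class PredictionSet:
    """Pooled actual/predicted pairs over all test months for one model."""

    months: pd.PeriodIndex
    actual: np.ndarray
    predicted: np.ndarray
    model_id: str

    def __post_init__(self):
        if len(self.actual) != len(self.predicted):
            raise ValueError("actual and predicted must align")


@dataclass(frozen=True)
class MetricsReport:
    pearson_r: float
    mae: float
    smape: float
    r_p_value: float = float("nan")


@dataclass(frozen=True)
class PermutationSummary:
    mean_r: float
    mean_smape: float
    prob_better: float
    n_perm: int


@dataclass(frozen=True)
class ComparisonResult:
    metrics_m0: MetricsReport
    metrics_m1: MetricsReport
    delta_r_percent: float
    delta_smape_percent: float
    steiger_t: float
    steiger_p: float


class _ConstantForecaster:
    """Degenerate fit used when the training series has zero variance."""

    def __init__(self, value: float):
        self.value = value
        self.aic = -np.inf

    def predict_indices(self, idx: np.ndarray) -> np.ndarray:
        return np.full(len(idx), self.value)

    def forecast(self, steps: int, exog=None) -> np.ndarray:
        return np.full(steps, self.value)


class _SarimaxFit:
    def __init__(self, results):
        self.results = results
        self.aic = float(results.aic)

    def predict_indices(self, idx: np.ndarray) -> np.ndarray:
        pred = self.results.get_prediction(
            start=int(idx.min()), end=int(idx.max())
        ).predicted_mean
        pred = np.asarray(pred)
        return pred[idx - int(idx.min())]

    def forecast(self, steps: int, exog=None) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(self.results.forecast(steps=steps, exog=exog))


def _fit_one(y, exog, order, seasonal_order):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = SARIMAX(
                y, exog=exog, order=order, seasonal_order=seasonal_order
            )
            return _SarimaxFit(model.fit(disp=0, maxiter=200))
        except Exception:
            # fall back to the unconstrained parameterization
            model = SARIMAX(
                y,
                exog=exog,
                order=order,
                seasonal_order=seasonal_order,
                enforce_stationarity=False,
                enforce_invertibility=False,
            )
            return _SarimaxFit(model.fit(disp=0, maxiter=200))


def select_orders(
    y: np.ndarray, exog: np.ndarray | None, cfg: ForecastConfig
) -> tuple[tuple[int, int, int], tuple[int, int, int, int]]:
    """AIC-minimizing (order, seasonal_order) over the configured grid."""
    if cfg.orders is not None:
        return cfg.orders
    best, best_aic = None, np.inf
    failures = []
    for order, seasonal in cfg.grid:
        try:
            fit = _fit_one(y, exog, order, seasonal)
        except Exception as err:  # non-convergence on this grid point
            failures.append((order, seasonal, str(err)))
            continue
        if np.isfinite(fit.aic) and fit.aic < best_aic:
            best, best_aic = (order, seasonal), fit.aic
    if best is None:
        raise RuntimeError(
            f"no SARIMA grid point converged; failures: {failures[:3]}"
        )
    return best


def fit_sarima(
    train: pd.Series | np.ndarray,
    exog: pd.DataFrame | np.ndarray | None = None,
    cfg: ForecastConfig | None = None,
):
    """Fit a SARIMA model with AIC order selection (or fixed orders)."""
    cfg = cfg or ForecastConfig()
    y = np.asarray(train, dtype=float)
    if len(y) < 24:
        raise ValueError("need at least 24 months of training data")
    X = None if exog is None else np.asarray(exog, dtype=float)
    if X is not None and len(X) != len(y):
        raise ValueError("exog must align with the training series")
    if np.ptp(y[~np.isnan(y)]) == 0:
        return _ConstantForecaster(float(y[~np.isnan(y)][0])), (
            (0, 0, 0), (0, 0, 0, cfg.seasonal_period)
        )
    orders = select_orders(y, X, cfg)
    return _fit_one(y, X, *orders), orders


def make_folds(n_months: int, cfg: ForecastConfig) -> list[np.ndarray]:
    """Contiguous test blocks over the non-anchor months."""
    non_anchor = np.arange(cfg.anchor, n_months)
    if cfg.k > len(non_anchor):
        raise ValueError("more folds than non-anchor months")
    return [b for b in np.array_split(non_anchor, cfg.k)]


def cv_predict(
    consult: pd.Series,
    exog: pd.DataFrame | None = None,
    cfg: ForecastConfig | None = None,
    model_id: str | None = None,
) -> PredictionSet:
    """Anchored k-fold cross-validated predictions, pooled over folds.

    Orders are selected once on the full series, then each fold refits
    the model with its test block masked as missing and reads off the
    Kalman-filter predictions for those months.
    """
    cfg = cfg or ForecastConfig()
    y = consult.to_numpy(dtype=float)
    n = len(y)
    if n < cfg.anchor + cfg.k:
        raise ValueError("series too short for the anchored fold scheme")
    X = None
    if exog is not None:
        exog = exog.loc[consult.index]
        if cfg.exog_lag > 0:
            exog = exog.shift(cfg.exog_lag).bfill()
        X = exog.to_numpy(dtype=float)
    if model_id is None:
        model_id = "M1" if X is not None else "M0"

    if np.ptp(y) == 0:
        fitted = _ConstantForecaster(float(y[0]))
        orders = None
    else:
        orders = select_orders(y, X, cfg)

    folds = make_folds(n, cfg)
    preds = np.full(n, np.nan)
    for test_idx in folds:
        if np.ptp(y) == 0:
            preds[test_idx] = fitted.predict_indices(test_idx)
            continue
        y_masked = y.copy()
        y_masked[test_idx] = np.nan
        fit = _fit_one(y_masked, X, *orders)
        preds[test_idx] = fit.predict_indices(test_idx)

    test_all = np.concatenate(folds)
    return PredictionSet(
        months=consult.index[test_all],
        actual=y[test_all],
        predicted=preds[test_all],
        model_id=model_id,
    )


def smape(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Symmetric mean absolute percentage error, bounded in [0, 100].

    Per-month term 100 * |y - x| / (|x| + |y|), averaged over months; a
    0/0 term counts as 0 (continuity).  This is the [0, 100]-bounded
    SMAPE variant; the common half-denominator form is exactly twice
    this, so relative comparisons between models are unaffected.
    """
    x = np.asarray(actual, float)
    y = np.asarray(predicted, float)
    denom = np.abs(x) + np.abs(y)
    terms = np.zeros(len(x))
    nz = denom > 0
    terms[nz] = np.abs(y[nz] - x[nz]) / denom[nz]
    return float(100.0 * terms.mean())


def metrics(pred: PredictionSet) -> MetricsReport:
    """Pearson's r, MAE and SMAPE of pooled predictions."""
    x, y = pred.actual, pred.predicted
    if len(x) < 3:
        raise ValueError("need at least 3 pooled months")
    mae = float(np.abs(y - x).mean())
    s = smape(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MetricsReport(float("nan"), mae, s, float("nan"))
    r, p = stats.pearsonr(x, y)
    return MetricsReport(float(r), mae, s, float(p))


def permutation_test(
    pred: PredictionSet, n_perm: int = 1000, seed: int = 0
) -> PermutationSummary:
    """Null distribution from shuffling predictions across months.

    Reports the mean permuted r and SMAPE and the fraction of
    permutations that beat the real model (higher r AND lower SMAPE).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null")
    rng = np.random.default_rng(seed)
    real = metrics(pred)
    x, y = pred.actual, pred.predicted
    rs = np.empty(n_perm)
    ss = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        rs[i] = stats.pearsonr(x, yp)[0] if np.ptp(yp) > 0 else 0.0
        ss[i] = smape(x, yp)
    better = (rs > real.pearson_r) & (ss < real.smape)
    return PermutationSummary(
        mean_r=float(rs.mean()),
        mean_smape=float(ss.mean()),
        prob_better=float(better.mean()),
        n_perm=n_perm,
    )


def dependent_overlap_test(
    actual: np.ndarray, pred0: np.ndarray, pred1: np.ndarray
) -> tuple[float, float]:
    """Williams/Steiger t-test for two correlations sharing a variable.

    Compares r(actual, pred0) against r(actual, pred1) accounting for
    r(pred0, pred1).  Positive t means pred0 correlates more strongly;
    a model-1 advantage therefore shows up as negative t.  Returns
    (t, two-sided p) with n - 3 degrees of freedom.
    """
    x = np.asarray(actual, float)
    y0 = np.asarray(pred0, float)
    y1 = np.asarray(pred1, float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 aligned months")
    for v in (x, y0, y1):
        if np.ptp(v) == 0:
            raise ValueError("zero-variance input")
    r12 = stats.pearsonr(x, y0)[0]
    r13 = stats.pearsonr(x, y1)[0]
    r23 = stats.pearsonr(y0, y1)[0]
    if np.allclose(y0, y1):
        return 0.0, 1.0
    detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    rbar = (r12 + r13) / 2.0
    denom = 2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
    if denom <= 0:
        return 0.0, 1.0
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def relative_improvement(baseline: float, improved: float) -> float:
    """Percent change relative to the baseline (positive = improvement
    for r; use (base - new)/base for errors)."""
    return 100.0 * (improved - baseline) / baseline


def compare_models(pred0: PredictionSet, pred1: PredictionSet) -> ComparisonResult:
    """Head-to-head comparison of pooled M0 and M1 predictions."""
    if not (pred0.months == pred1.months).all():
        raise ValueError("M0 and M1 must cover the same months")
    m0 = metrics(pred0)
    m1 = metrics(pred1)
    t, p = dependent_overlap_test(pred0.actual, pred0.predicted, pred1.predicted)
    return ComparisonResult(
        metrics_m0=m0,
        metrics_m1=m1,
        delta_r_percent=relative_improvement(m0.pearson_r, m1.pearson_r),
        delta_smape_percent=100.0 * (m0.smape - m1.smape) / m0.smape,
        steiger_t=t,
        steiger_p=p,
    )
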