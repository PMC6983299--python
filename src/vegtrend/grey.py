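"""GM(1,1) grey forecasting with residual, relational-grade and posterior
difference diagnostics.

The GM(1,1) model turns a short positive series x0 into its accumulated sum
x1 (AGO), fits the whitened differential equation

    dx1/dt + alpha * x1 = beta

by least squares on x0(k) = -alpha * z1(k) + beta, where
z1(k) = (x1(k) + x1(k-1)) / 2, and forecasts through the closed form

    X1(k+1) = (x0(1) - beta/alpha) * exp(-alpha * k) + beta/alpha

with predictions recovered by first differencing (inverse AGO).  alpha is
the development coefficient (growth/decay rate), beta the grey action
(level term).  The model is exact on geometric series x0(k) = A * q^(k-1).

Diagnostics follow grey-systems practice: per-year residuals and similarity
percentages, the grey relational grade R (mean of relational coefficients
xi(k) with resolution coefficient rho, default 0.5, passing when R > 0.5),
and the posterior difference ratio C = sd(residual)/sd(measured) with the
conventional 0.35 / 0.5 / 0.65 grade thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import AnnualSeries, ValidationError

_ALPHA_LINEAR_LIMIT = 1e-12


def ago(values: np.ndarray) -> np.ndarray:
    """Accumulated generating operation: running sum, first element kept."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("ago: empty input")
    return np.cumsum(x)


def inverse_ago(accumulated: np.ndarray) -> np.ndarray:
    """First differencing; exact inverse of :func:`ago`."""
    x1 = np.asarray(accumulated, dtype=np.float64)
    if x1.size == 0:
        raise ValidationError("inverse_ago: empty input")
    return np.concatenate([[x1[0]], np.diff(x1)])


@dataclass(frozen=True)
class GM11Model:
    """Fitted GM(1,1) model.

    ``c_exp`` and ``c_const`` are the closed-form constants
    x0(1) - beta/alpha and beta/alpha, so c_exp + c_const == x0(1).
    """

    alpha: float
    beta: float
    x0_1: float
    start_year: int
    n_fit: int
    fitted_values: np.ndarray = field(repr=False)

    @property
    def c_const(self) -> float:
        if abs(self.alpha) < _ALPHA_LINEAR_LIMIT:
            return np.nan
        return self.beta / self.alpha

    @property
    def c_exp(self) -> float:
        if abs(self.alpha) < _ALPHA_LINEAR_LIMIT:
            return np.nan
        return self.x0_1 - self.beta / self.alpha


def class_ratio_check(values: np.ndarray) -> bool:
    """Admissibility check sigma(k) = x0(k-1)/x0(k) in (e^-2/(n+1), e^2/(n+1)).

    Emits a warning (not an error) when violated; GM(1,1) forecasts from
    inadmissible series are unreliable.
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    ratios = x[:-1] / x[1:]
    lo, hi = np.exp(-2.0 / (n + 1)), np.exp(2.0 / (n + 1))
    ok = bool(np.all((ratios > lo) & (ratios < hi)))
    if not ok:
        warnings.warn(
            "series fails the GM(1,1) class-ratio admissibility check; "
            "forecasts may be unreliable",
            stacklevel=3,
        )
    return ok


def fit_gm11(series: AnnualSeries, check_admissibility: bool = True) -> GM11Model:
    """Fit GM(1,1) by least squares on the mean-sequence regression."""
    x0 = np.asarray(series.values, dtype=np.float64)
    if x0.size < 4:
        raise ValidationError(f"fit_gm11 requires n >= 4, got {x0.size}")
    if np.any(x0 <= 0):
        raise ValidationError("fit_gm11 requires strictly positive values")
    if check_admissibility:
        class_ratio_check(x0)
    x1 = ago(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z1, np.ones(z1.size)])
    coef, *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    model = GM11Model(
        alpha=alpha,
        beta=beta,
        x0_1=float(x0[0]),
        start_year=series.start_year,
        n_fit=x0.size,
        fitted_values=np.empty(0),
    )
    fitted = _predict_x0(model, x0.size)
    object.__setattr__(model, "fitted_values", fitted)
    return model


def _predict_x1(model: GM11Model, n: int) -> np.ndarray:
    """Closed-form accumulated series X1(k), k = 1..n."""
    k = np.arange(n, dtype=np.float64)  # exponent k-1 for the k-th element
    if abs(model.alpha) < _ALPHA_LINEAR_LIMIT:
        return model.x0_1 + model.beta * k
    return model.c_exp * np.exp(-model.alpha * k) + model.c_const


def _predict_x0(model: GM11Model, n: int) -> np.ndarray:
    x1 = _predict_x1(model, n)
    x0 = inverse_ago(x1)
    x0[0] = model.x0_1  # standard convention: fitted first value = observed
    return x0


def forecast(model: GM11Model, horizon: int = 0) -> AnnualSeries:
    """Fitted plus forecast series: n_fit in-sample years + ``horizon`` more."""
    if horizon < 0:
        raise ValidationError("horizon must be >= 0")
    n = model.n_fit + horizon
    values = _predict_x0(model, n)
    years = np.arange(model.start_year, model.start_year + n)
    return AnnualSeries(years, values, "predicted")


def rolling_gm11(series: AnnualSeries, window: int) -> AnnualSeries:
    """One-step-ahead predictions refitting GM(1,1) on a trailing window.

    A light 'metabolic' variant: for each year beyond the first ``window``
    years, the model is refit on the most recent ``window`` observations
    and its one-step forecast recorded.
    """
    if window < 4:
        raise ValidationError("rolling window must be >= 4")
    if window >= len(series):
        raise ValidationError("rolling window must be shorter than the series")
    years, preds = [], []
    for end in range(window, len(series)):
        sub = AnnualSeries(
            series.years[end - window : end],
            series.values[end - window : end],
            series.name,
        )
        m = fit_gm11(sub, check_admissibility=False)
        preds.append(forecast(m, horizon=1).values[-1])
        years.append(int(series.years[end]))
    return AnnualSeries(np.array(years), np.array(preds), "predicted")


@dataclass(frozen=True)
class ForecastDiagnostics:
    """Residual table plus relational-grade and posterior-ratio summaries."""

    table: pd.DataFrame  # year, measured, predicted, difference, similarity_pct
    relational_grade: float
    rho: float
    pass_50pct: bool
    posterior_ratio: float
    posterior_grade: str


def residual_table(measured: AnnualSeries, predicted: AnnualSeries) -> pd.DataFrame:
    """Per-year difference (predicted - measured) and similarity percentage.

    similarity_pct = 100 * (1 - |difference| / measured); the displayed
    column is rounded half away from zero to 2 decimals, full precision is
    kept in 'similarity_pct_exact'.
    """
    if not np.array_equal(measured.years, predicted.years):
        raise ValidationError("measured and predicted series cover different years")
    m = measured.values
    if np.any(m <= 0):
        raise ValidationError("similarity undefined for non-positive measured values")
    diff = predicted.values - m
    sim = 100.0 * (1.0 - np.abs(diff) / m)
    # round half away from zero at 2 d.p. for display
    sim_display = np.sign(sim) * np.floor(np.abs(sim) * 100 + 0.5) / 100
    return pd.DataFrame(
        {
            "year": measured.years,
            "measured": m,
            "predicted": predicted.values,
            "difference": diff,
            "similarity_pct": sim_display,
            "similarity_pct_exact": sim,
        }
    )


def relational_grade(
    measured: np.ndarray, predicted: np.ndarray, rho: float = 0.5
) -> tuple[np.ndarray, float]:
    """Grey relational coefficients xi(k) and their mean R.

    xi(k) = (dmin + rho*dmax) / (d(k) + rho*dmax) over the absolute
    differences d(k); when every d(k) = 0 the 0/0 convention gives xi = 1.
    R > 0.5 is the conventional pass level.
    """
    m = np.asarray(measured, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if m.shape != p.shape:
        raise ValidationError("length mismatch between measured and predicted")
    if m.size < 2:
        raise ValidationError("relational_grade requires >= 2 points")
    if not (0 < rho <= 1):
        raise ValidationError("rho must be in (0, 1]")
    delta = np.abs(m - p)
    dmin, dmax = delta.min(), delta.max()
    if dmax == 0.0:
        xi = np.ones_like(delta)
    else:
        xi = (dmin + rho * dmax) / (delta + rho * dmax)
    return xi, float(xi.mean())


_POSTERIOR_GRADES = ((0.35, "excellent"), (0.50, "good"), (0.65, "qualified"))


def posterior_ratio(measured: np.ndarray, predicted: np.ndarray) -> tuple[float, str]:
    """Posterior difference ratio C = sd(residual) / sd(measured).

    Small C means the model captured most of the variance; grades follow
    the conventional thresholds (<0.35 excellent, <0.5 good, <0.65
    qualified, else unqualified).
    """
    m = np.asarray(measured, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if m.shape != p.shape:
        raise ValidationError("length mismatch between measured and predicted")
    if m.size < 2:
        raise ValidationError("posterior_ratio requires >= 2 points")
    sd_m = m.std(ddof=1)
    if sd_m == 0.0:
        raise ValidationError("measured series has zero variance")
    c = float((m - p).std(ddof=1) / sd_m)
    for thr, label in _POSTERIOR_GRADES:
        if c < thr:
            return c, label
    return c, "unqualified"


def percent_change(baseline: float, target: float) -> float:
    """Relative change of ``target`` versus ``baseline``, in percent."""
    if baseline <= 0:
        raise ValidationError("baseline must be > 0")
    return 100.0 * (target - baseline) / baseline


def diagnose(
    measured: AnnualSeries, predicted: AnnualSeries, rho: float = 0.5
) -> ForecastDiagnostics:
    """Full diagnostic bundle for a fitted/forecast comparison."""
    table = residual_table(measured, predicted)
    _, grade = relational_grade(measured.values, predicted.values, rho)
    c, label = posterior_ratio(measured.values, predicted.values)
    return ForecastDiagnostics(
        table=table,
        relational_grade=grade,
        rho=rho,
        pass_50pct=grade > 0.5,
        posterior_ratio=c,
        posterior_grade=label,
    )
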