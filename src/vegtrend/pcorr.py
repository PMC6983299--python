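"""Full-order partial correlation of a response against climate covariates.

For a panel of jointly observed annual variables, the partial correlation of
the response with covariate v, controlling all remaining covariates, comes
from the inverse of the full correlation matrix P:

    r_ij.rest = -P_ij / sqrt(P_ii * P_jj)

which equals the correlation of the residuals after regressing both
variables on the controls.  Significance uses Student's t with n - p - 2
degrees of freedom, where p is the number of controlled covariates:

    t = r * sqrt((n - p - 2) / (1 - r^2))        (mode "standard")

An alternative statistic t = r * sqrt((n - p - 1) / (1 + r^2)) is offered
as mode "as_printed" for comparability with reports that use that form; it
is not recommended (it is not monotone-equivalent to the standard test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .series import ValidationError
from .trend import stars_for_p

TestMode = Literal["standard", "as_printed"]


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial correlation of the response with one covariate."""

    covariate: str
    r_partial: float
    t_stat: float
    p_value: float
    n: int
    p_controlled: int
    window: tuple[int, int]
    stars: str


def partial_corr_test(
    r: float, n: int, p: int, mode: TestMode = "standard"
) -> tuple[float, float]:
    """t statistic and two-sided p for a partial correlation coefficient.

    ``n`` is the number of observations, ``p`` the number of controlled
    covariates.  Requires n - p - 2 >= 1.
    """
    if abs(r) > 1 + 1e-12:
        raise ValidationError(f"|r| = {abs(r)} > 1")
    r = float(np.clip(r, -1.0, 1.0))
    df = n - p - 2
    if df < 1:
        raise ValidationError(f"n - p - 2 = {df} < 1: too few observations")
    if mode == "as_printed":
        t = r * np.sqrt((n - p - 1) / (1.0 + r * r))
    elif mode == "standard":
        if abs(r) == 1.0:
            return float(np.copysign(np.inf, r)), 0.0
        t = r * np.sqrt(df / (1.0 - r * r))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p_value = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p_value)


def _collinear_pairs(panel: pd.DataFrame, corr: np.ndarray) -> list[tuple[str, str]]:
    return [
        (str(panel.columns[j]), str(panel.columns[i]))
        for i in range(corr.shape[0])
        for j in range(i)
        if abs(corr[i, j]) > 1 - 1e-10
    ]


def _partial_corr_matrix(panel: pd.DataFrame) -> np.ndarray | None:
    """Full-order partial correlation matrix from the precision matrix.

    Returns None when the full correlation matrix is singular (the caller
    falls back to the residual-regression route, which remains defined when
    only the response/covariate pair is collinear).
    """
    corr = np.corrcoef(panel.to_numpy(), rowvar=False)
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or logdet < np.log(1e-14) * corr.shape[0]:
        return None
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def _residual_partial_corr(panel: pd.DataFrame, response: str, cov: str) -> float:
    """Residual-regression definition of the full-order partial correlation,
    used when the full correlation matrix is singular.

    Degenerate cases: a perfectly collinear response/covariate pair gives
    +-1; a response fully explained by the controls alone gives 0 (nothing
    left to correlate); a covariate collinear with the controls is an error
    (the coefficient is 0/0 with no meaningful value).
    """
    raw = float(np.corrcoef(panel[response], panel[cov])[0, 1])
    if abs(raw) > 1 - 1e-12:
        return float(np.sign(raw))
    others = [c for c in panel.columns if c not in (response, cov)]
    X = np.column_stack(
        [np.ones(len(panel))] + [panel[c].to_numpy() for c in others]
    )
    resid = {}
    for v in (response, cov):
        y = panel[v].to_numpy()
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[v] = y - X @ coef
    if np.std(resid[cov]) < 1e-12 * max(1.0, float(np.std(panel[cov]))):
        corr = np.corrcoef(panel.to_numpy(), rowvar=False)
        raise ValidationError(
            "correlation matrix is singular; collinear variables: "
            f"{_collinear_pairs(panel, corr)}"
        )
    if np.std(resid[response]) < 1e-12 * max(1.0, float(np.std(panel[response]))):
        return 0.0
    return float(np.clip(np.corrcoef(resid[response], resid[cov])[0, 1], -1.0, 1.0))


def partial_corr_all(
    panel: pd.DataFrame,
    response: str,
    mode: TestMode = "standard",
) -> list[PartialCorrResult]:
    """Partial correlation of ``response`` with each covariate, controlling
    all other covariates.

    ``panel`` is a DataFrame indexed by year, one column per variable.
    """
    if response not in panel.columns:
        raise ValidationError(f"response {response!r} not in panel")
    if panel.isna().any().any():
        raise ValidationError("panel contains missing values")
    names = list(panel.columns)
    n = len(panel)
    n_covariates = len(names) - 1
    if n < n_covariates + 3:
        raise ValidationError(
            f"need at least {n_covariates + 3} years for {n_covariates} "
            f"covariates, got {n}"
        )
    pc = _partial_corr_matrix(panel)
    i = names.index(response)
    years = panel.index.to_numpy()
    window = (int(years.min()), int(years.max()))
    p_controlled = n_covariates - 1
    results = []
    for j, name in enumerate(names):
        if j == i:
            continue
        if pc is not None:
            r = float(pc[i, j])
        else:
            r = _residual_partial_corr(panel, response, name)
        t, p_value = partial_corr_test(r, n, p_controlled, mode)
        results.append(
            PartialCorrResult(
                covariate=name,
                r_partial=r,
                t_stat=t,
                p_value=p_value,
                n=n,
                p_controlled=p_controlled,
                window=window,
                stars=stars_for_p(p_value),
            )
        )
    return results


def windowed_analysis(
    panel: pd.DataFrame,
    response: str,
    windows: Sequence[tuple[int, int]],
    mode: TestMode = "standard",
) -> dict[tuple[int, int], list[PartialCorrResult]]:
    """Run partial_corr_all over several year windows (e.g. full period and
    the pre/post change-point halves)."""
    years = panel.index.to_numpy()
    out: dict[tuple[int, int], list[PartialCorrResult]] = {}
    for start, end in windows:
        if start < years.min() or end > years.max():
            raise ValidationError(
                f"window {start}-{end} outside panel range "
                f"{years.min()}-{years.max()}"
            )
        sub = panel.loc[start:end]
        out[(start, end)] = partial_corr_all(sub, response, mode)
    return out
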