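"""Mann-Kendall trend testing, Theil-Sen slopes and sequential change-point
detection for annual series, scalar and pixel-wise.

The Mann-Kendall statistic S counts concordant minus discordant pairs; its
variance carries the standard tied-group correction

    Var(S) = [n(n-1)(2n+5) - sum_k t_k(t_k-1)(2t_k+5)] / 18

with t_k the size of each tied group.  Z applies the +-1 continuity
correction (Z=0 at S=0) and is referred to the standard normal two-sided.
The Theil-Sen slope is the median of all pairwise slopes; per-decade rates
are 10x the annual slope, the reporting convention of regional NDVI studies.

Sequential change-point detection follows Sneyers: the progressive (UF) and
retrograde (UB) standardized rank statistics cross near an abrupt change in
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import AnnualSeries, GridStack, ValidationError


def stars_for_p(p: float, alpha1: float = 0.05, alpha2: float = 0.01) -> str:
    """Two-level significance stars: '**' below alpha2, '*' below alpha1."""
    if p < alpha2:
        return "**"
    if p < alpha1:
        return "*"
    return ""


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall / Theil-Sen summary for one series."""

    n: int
    s: float
    var_s: float
    z: float
    p_two_sided: float
    sen_slope: float
    ols_slope: float
    stars: str

    @property
    def slope_per_decade(self) -> float:
        return 10.0 * self.sen_slope


@dataclass(frozen=True)
class ChangePointResult:
    """Sneyers sequential MK statistics and their in-band crossings."""

    years: np.ndarray
    uf: np.ndarray
    ub: np.ndarray
    crossings: tuple[int, ...]
    alpha: float


def _check_series(series: AnnualSeries, n_min: int, what: str) -> np.ndarray:
    x = np.asarray(series.values, dtype=np.float64)
    if x.size < n_min:
        raise ValidationError(f"{what} requires n >= {n_min}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{what}: series contains non-finite values")
    return x


def mk_s_statistic(values: np.ndarray) -> float:
    """S = sum over i>j of sign(x_i - x_j), vectorized."""
    x = np.asarray(values, dtype=np.float64)
    sgn = np.sign(x[:, None] - x[None, :])
    return float(np.sum(np.triu(sgn.T, k=1)))


def mk_variance(values: np.ndarray) -> float:
    """Tie-corrected variance of S."""
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    correction = np.sum(ties * (ties - 1) * (2 * ties + 5)) if ties.size else 0.0
    return (n * (n - 1) * (2 * n + 5) - correction) / 18.0


def mk_test(series: AnnualSeries) -> TrendResult:
    """Mann-Kendall trend test with tie correction and Sen/OLS slopes."""
    x = _check_series(series, 4, "mk_test")
    s = mk_s_statistic(x)
    var_s = mk_variance(x)
    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(
        n=x.size,
        s=s,
        var_s=var_s,
        z=float(z),
        p_two_sided=float(p),
        sen_slope=sen_slope(series),
        ols_slope=ols_slope(series),
        stars=stars_for_p(p),
    )


def sen_slope(series: AnnualSeries) -> float:
    """Theil-Sen slope: median of (x_i - x_j)/(i - j) over all pairs."""
    if len(series) < 2:
        raise ValidationError("sen_slope requires n >= 2")
    slope, _, _, _ = stats.theilslopes(series.values, series.years)
    return float(slope)


def ols_slope(series: AnnualSeries) -> float:
    """Ordinary least-squares slope of value on year."""
    if len(series) < 2:
        raise ValidationError("ols_slope requires n >= 2")
    res = stats.linregress(series.years, series.values)
    return float(res.slope)


def _sequential_uf(x: np.ndarray) -> np.ndarray:
    """Sneyers progressive statistic over prefixes of length k = 1..n.

    Uses the signed pair-count form S_k / sqrt(k(k-1)(2k+5)/18), identical
    to the exceedance-count formulation for distinct values and unbiased
    (E[S_k] = 0) in the presence of ties.
    """
    n = x.size
    sgn = np.sign(x[:, None] - x[None, :])  # sgn[i, j] = sign(x_i - x_j)
    r = np.array([sgn[i, :i].sum() for i in range(n)], dtype=np.float64)
    sk = np.cumsum(r)
    k = np.arange(1, n + 1, dtype=np.float64)
    var = k * (k - 1) * (2 * k + 5) / 18.0
    uf = np.zeros(n)
    valid = var > 0
    uf[valid] = sk[valid] / np.sqrt(var[valid])
    return uf


def sequential_mk(series: AnnualSeries, alpha: float = 0.05) -> ChangePointResult:
    """Sequential Mann-Kendall change-point detection (UF/UB crossing).

    UF is the progressive statistic, UB the negated retrograde one
    (computed on the reversed series).  Crossings are reported where
    UF - UB changes sign with both curves inside the +-z_{1-alpha/2}
    confidence band; the crossing year is the later year of the sign
    change, the conventional reading of the intersection plot.
    """
    x = _check_series(series, 10, "sequential_mk")
    uf = _sequential_uf(x)
    ub = -_sequential_uf(x[::-1])[::-1]
    band = stats.norm.ppf(1.0 - alpha / 2.0)
    diff = uf - ub
    crossings: list[int] = []
    for i in range(1, x.size):
        d0, d1 = diff[i - 1], diff[i]
        crossed = (d1 == 0.0 and d0 != 0.0) or (d0 != 0.0 and np.sign(d0) != np.sign(d1))
        if not crossed:
            continue
        inside = (abs(uf[i]) <= band and abs(ub[i]) <= band) or (
            abs(uf[i - 1]) <= band and abs(ub[i - 1]) <= band
        )
        if inside:
            crossings.append(int(series.years[i]))
    return ChangePointResult(
        years=series.years.copy(),
        uf=uf,
        ub=ub,
        crossings=tuple(crossings),
        alpha=alpha,
    )


def pixelwise_trend(stack: GridStack) -> dict[str, np.ma.MaskedArray]:
    """Apply mk_test + sen_slope to every unmasked pixel of a stack.

    Returns masked arrays 'sen_slope', 'slope_per_decade', 'z', 'p' and an
    object-dtype 'stars' map; masked pixels are masked everywhere.
    """
    if not stack.mask.any():
        raise ValidationError("all pixels are masked")
    if stack.years.size < 4:
        raise ValidationError("pixelwise_trend requires >= 4 years")
    shape = stack.shape
    slope = np.full(shape, np.nan)
    z = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    stars = np.full(shape, "", dtype=object)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if not stack.mask[r, c]:
                continue
            res = mk_test(stack.pixel_series(r, c))
            slope[r, c] = res.sen_slope
            z[r, c] = res.z
            p[r, c] = res.p_two_sided
            stars[r, c] = res.stars
    invalid = ~stack.mask
    return {
        "sen_slope": np.ma.MaskedArray(slope, mask=invalid),
        "slope_per_decade": np.ma.MaskedArray(10.0 * slope, mask=invalid),
        "z": np.ma.MaskedArray(z, mask=invalid),
        "p": np.ma.MaskedArray(p, mask=invalid),
        "stars": np.ma.MaskedArray(stars, mask=invalid),
    }
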