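"""Synthetic annual-series, covariate-panel and grid-stack generators.

These provide ground-truth fixtures for every pipeline stage: a piecewise
linear NDVI-like series (default segment rates 0.0016/yr up, -0.0025/yr
down, 0.0033/yr up over 1981-2018), covariate panels drawn from a
multivariate normal with a prescribed precision matrix (hence known partial
correlations), and small raster stacks with a per-pixel slope field.

Noise is AR(1) Gaussian: annual climate and greenness series carry lag-1
autocorrelation, and ``ar1=0`` recovers i.i.d. noise.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .series import AnnualSeries, GridStack, ValidationError


@dataclass(frozen=True)
class SegmentSpec:
    """One linear segment of a piecewise trend, inclusive year bounds."""

    start_year: int
    end_year: int
    slope: float  # value units per year

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValidationError(
                f"segment start {self.start_year} after end {self.end_year}"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """AR(1) Gaussian noise: e_t = ar1 * e_{t-1} + N(0, sigma^2)."""

    sigma: float = 0.0
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if not abs(self.ar1) < 1:
            raise ValidationError("|ar1| must be < 1")


@dataclass(frozen=True)
class CovariancePanelSpec:
    """Multivariate-normal panel defined through its precision matrix.

    The partial correlation of variables i, j given all others is
    -P_ij / sqrt(P_ii * P_jj), so the precision matrix *is* the ground
    truth for partial-correlation recovery tests.
    """

    n_years: int
    precision_matrix: np.ndarray
    names: Sequence[str]
    seed: int = 0
    start_year: int = 1981

    def __post_init__(self) -> None:
        P = np.asarray(self.precision_matrix, dtype=np.float64)
        object.__setattr__(self, "precision_matrix", P)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValidationError("precision matrix must be square")
        if len(self.names) != P.shape[0]:
            raise ValidationError(
                f"{len(self.names)} names for {P.shape[0]}-variable precision"
            )
        if not np.allclose(P, P.T):
            raise ValidationError("precision matrix must be symmetric")
        try:
            np.linalg.cholesky(P)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("precision matrix not positive definite") from exc

    def implied_partial_corr(self, i: int, j: int) -> float:
        """Partial correlation of variables i, j given all the rest."""
        P = self.precision_matrix
        return float(-P[i, j] / np.sqrt(P[i, i] * P[j, j]))


def _ar1_noise(n: int, noise: NoiseSpec) -> np.ndarray:
    """Stationary AR(1) draw; sigma is the innovation standard deviation."""
    if noise.sigma == 0:
        return np.zeros(n)
    rng = np.random.default_rng(noise.seed)
    e = np.empty(n)
    # stationary initial condition so the marginal variance is constant
    e[0] = rng.normal(0.0, noise.sigma / np.sqrt(1.0 - noise.ar1**2))
    innov = rng.normal(0.0, noise.sigma, size=n - 1)
    for t in range(1, n):
        e[t] = noise.ar1 * e[t - 1] + innov[t - 1]
    return e


def gen_piecewise_series(
    segments: Sequence[SegmentSpec],
    intercept: float,
    noise: NoiseSpec = NoiseSpec(),
    name: str = "NDVI",
) -> AnnualSeries:
    """Piecewise-linear annual series with value-continuous segment joins.

    The first year of the first segment takes ``intercept``; each later year
    advances by the slope of the segment containing it, so the series is
    continuous across segment boundaries.
    """
    if not segments:
        raise ValidationError("no segments given")
    segs = sorted(segments, key=lambda s: s.start_year)
    for a, b in zip(segs[:-1], segs[1:]):
        if b.start_year != a.end_year + 1:
            raise ValidationError(
                f"segments must be contiguous: {a.end_year} then {b.start_year}"
            )
    years = np.arange(segs[0].start_year, segs[-1].end_year + 1)
    # per-year increment = slope of the segment containing that year
    slopes = np.empty(years.size)
    for seg in segs:
        slopes[(years >= seg.start_year) & (years <= seg.end_year)] = seg.slope
    values = intercept + np.concatenate([[0.0], np.cumsum(slopes[1:])])
    values = values + _ar1_noise(years.size, noise)
    return AnnualSeries(years, values, name)


DEFAULT_SEGMENTS = (
    SegmentSpec(1981, 1997, 0.0016),
    SegmentSpec(1998, 2009, -0.0025),
    SegmentSpec(2010, 2018, 0.0033),
)
DEFAULT_INTERCEPT = 0.2876


def default_ndvi_fixture(noise: NoiseSpec = NoiseSpec()) -> AnnualSeries:
    """The study-shaped fixture: 1981-2018 with staged up/down/up trends."""
    return gen_piecewise_series(DEFAULT_SEGMENTS, DEFAULT_INTERCEPT, noise)


def gen_covariate_panel(spec: CovariancePanelSpec) -> pd.DataFrame:
    """Draw an annual panel from N(0, precision^-1).

    Returns a DataFrame indexed by year with one column per variable;
    rows are i.i.d. across years.
    """
    cov = np.linalg.inv(spec.precision_matrix)
    rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal(
        np.zeros(cov.shape[0]), cov, size=spec.n_years, method="cholesky"
    )
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    return pd.DataFrame(draws, index=pd.Index(years, name="year"),
                        columns=list(spec.names))


def panel_to_series(panel: pd.DataFrame) -> dict[str, AnnualSeries]:
    """View a panel as a dict of AnnualSeries keyed by variable name."""
    years = panel.index.to_numpy()
    return {c: AnnualSeries(years, panel[c].to_numpy(), c) for c in panel.columns}


def gen_grid_stack(
    n_years: int,
    shape: tuple[int, int],
    slope_field: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
    intercept: float = 0.3,
    start_year: int = 1981,
    mask: np.ndarray | None = None,
) -> GridStack:
    """Linear-plus-noise series at every pixel, each with its own slope.

    ``mask`` marks valid pixels (True); masked pixels carry NaN in every
    layer and stay masked downstream.
    """
    slope_field = np.asarray(slope_field, dtype=np.float64)
    if slope_field.shape != tuple(shape):
        raise ValidationError(
            f"slope_field shape {slope_field.shape} != grid shape {tuple(shape)}"
        )
    if n_years < 1 or shape[0] < 1 or shape[1] < 1:
        raise ValidationError("n_years and shape must be positive")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValidationError("mask shape mismatch")
    years = np.arange(start_year, start_year + n_years)
    t = np.arange(n_years)[:, None, None]
    data = intercept + t * slope_field[None, :, :]
    if noise.sigma > 0:
        rng_seed = noise.seed
        for r in range(shape[0]):
            for c in range(shape[1]):
                px_noise = NoiseSpec(noise.sigma, noise.ar1,
                                     rng_seed + r * shape[1] + c)
                data[:, r, c] += _ar1_noise(n_years, px_noise)
    data[:, ~mask] = np.nan
    return GridStack(years, data, mask)
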