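"""Core containers: annual time series and gridded annual stacks.

An :class:`AnnualSeries` is one variable observed once per calendar year over
a gap-free window (e.g. area-mean NDVI 1981-2018).  A :class:`GridStack` is
the pixel-wise analogue: a (year, row, col) cube with a validity mask, the
in-memory form of an annual raster stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when input data violate a container invariant."""


@dataclass(frozen=True)
class AnnualSeries:
    """A gap-free annual series of one variable.

    Parameters
    ----------
    years
        Strictly increasing consecutive calendar years.
    values
        Finite observations, one per year.
    name
        Variable label (used in tables and error messages).
    """

    years: np.ndarray
    values: np.ndarray
    name: str = "value"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1:
            raise ValidationError("years and values must be 1-D")
        if years.size != values.size:
            raise ValidationError(
                f"length mismatch: {years.size} years vs {values.size} values"
            )
        if years.size == 0:
            raise ValidationError("empty series")
        steps = np.diff(years)
        if np.any(steps != 1):
            missing = []
            for y0, y1 in zip(years[:-1], years[1:]):
                if y1 <= y0:
                    raise ValidationError(f"years not strictly increasing at {y1}")
                missing.extend(range(y0 + 1, y1))
            raise ValidationError(f"gap in years; missing {missing}")
        if not np.all(np.isfinite(values)):
            bad = years[~np.isfinite(values)]
            raise ValidationError(f"non-finite values at years {bad.tolist()}")

    def __len__(self) -> int:
        return int(self.years.size)

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def window(self, start: int, end: int) -> "AnnualSeries":
        """Return the sub-series covering ``start``..``end`` inclusive."""
        if start < self.start_year or end > self.end_year:
            raise ValidationError(
                f"window {start}-{end} outside series range "
                f"{self.start_year}-{self.end_year}"
            )
        if end < start:
            raise ValidationError(f"window end {end} before start {start}")
        sel = (self.years >= start) & (self.years <= end)
        return AnnualSeries(self.years[sel], self.values[sel], self.name)


@dataclass
class GridStack:
    """Annual raster stack: data[year, row, col] with a per-pixel mask.

    ``mask`` is True where a pixel is valid; invalid pixels are invalid for
    every year (nodata propagates through the whole series).
    ``geotransform`` is an optional 6-tuple (GDAL convention) carried as
    plain metadata.
    """

    years: np.ndarray
    data: np.ndarray
    mask: np.ndarray
    geotransform: tuple | None = field(default=None)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValidationError("data must be (year, row, col)")
        if self.years.size != self.data.shape[0]:
            raise ValidationError(
                f"{self.years.size} years but data has {self.data.shape[0]} layers"
            )
        if np.any(np.diff(self.years) <= 0):
            raise ValidationError("years must be strictly increasing")
        if self.mask.shape != self.data.shape[1:]:
            raise ValidationError(
                f"mask shape {self.mask.shape} != grid shape {self.data.shape[1:]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def pixel_series(self, row: int, col: int) -> AnnualSeries:
        """Extract one pixel's series (the pixel must be unmasked)."""
        if not self.mask[row, col]:
            raise ValidationError(f"pixel ({row}, {col}) is masked")
        return AnnualSeries(self.years, self.data[:, row, col], f"px_{row}_{col}")
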