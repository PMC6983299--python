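"""Readers and writers: annual-series CSV tables, grid stacks (NetCDF or a
directory of per-year TIFFs), and report tables in the standard regional
reporting schemas (starred per-decade trend rates, partial-correlation grids
by window, forecast accuracy tables).

All readers validate and reject rather than repair: gap years, duplicate
years and non-numeric cells are hard errors naming the offending row.
Unicode minus signs (common in copy-pasted tables) are normalized to ASCII
on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .series import AnnualSeries, GridStack, ValidationError

_MINUS = "−"


def _clean_numeric(s: pd.Series, column: str) -> pd.Series:
    if s.dtype == object:
        s = s.astype(str).str.strip().str.replace(_MINUS, "-", regex=False)
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & s.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"non-numeric cell in column {column!r} at data row {row}: "
            f"{s.iloc[row]!r}"
        )
    return out


def read_series_csv(path: str | Path, column: str) -> AnnualSeries:
    """Read one named column from a `year,<name>,...` CSV as an AnnualSeries."""
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValidationError(f"{path}: no 'year' column")
    if column not in df.columns:
        raise ValidationError(
            f"{path}: no column {column!r}; available: {list(df.columns)}"
        )
    years = _clean_numeric(df["year"], "year").to_numpy()
    if np.any(years != years.astype(int)):
        raise ValidationError(f"{path}: non-integer year values")
    years = years.astype(int)
    dup = pd.Series(years).duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate year {years[dup.idxmax()]}")
    order = np.argsort(years)
    years = years[order]
    gaps = [y for y0, y1 in zip(years[:-1], years[1:]) for y in range(y0 + 1, y1)]
    if gaps:
        raise ValidationError(f"{path}: missing years {gaps}")
    values = _clean_numeric(df[column], column).to_numpy()[order]
    return AnnualSeries(years, values, column)


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    """Read all value columns of a `year,...` CSV into a year-indexed panel."""
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValidationError(f"{path}: no 'year' column")
    names = [c for c in df.columns if c != "year"]
    series = {c: read_series_csv(path, c) for c in names}
    years = next(iter(series.values())).years
    return pd.DataFrame(
        {c: s.values for c, s in series.items()},
        index=pd.Index(years, name="year"),
    )


def write_series_csv(
    series_map: Mapping[str, AnnualSeries] | AnnualSeries, path: str | Path
) -> None:
    """Write one or several aligned series as `year,<name>,...` CSV."""
    if isinstance(series_map, AnnualSeries):
        series_map = {series_map.name: series_map}
    items = list(series_map.items())
    years = items[0][1].years
    for name, s in items[1:]:
        if not np.array_equal(s.years, years):
            raise ValidationError(f"series {name!r} covers different years")
    df = pd.DataFrame({"year": years})
    for name, s in items:
        df[name] = s.values
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid stacks

_NODATA = -9999.0


def write_grid_stack(stack: GridStack, path: str | Path) -> None:
    """Write a stack as NetCDF (dims year, y, x) or a per-year TIFF directory.

    A path ending in `.nc` gets NetCDF; otherwise the path is treated as a
    directory receiving one `<year>.tif` per layer.  Masked pixels are
    stored as the -9999 nodata value.
    """
    path = Path(path)
    data = stack.data.copy()
    data[:, ~stack.mask] = _NODATA
    if path.suffix == ".nc":
        ds = xr.Dataset(
            {"value": (("year", "y", "x"), data)},
            coords={"year": stack.years},
            attrs={"nodata": _NODATA},
        )
        if stack.geotransform is not None:
            ds.attrs["geotransform"] = list(stack.geotransform)
        ds.to_netcdf(path, engine="scipy")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, year in enumerate(stack.years):
            tifffile.imwrite(path / f"{year}.tif", data[i].astype(np.float64))


def read_grid_stack(path: str | Path) -> GridStack:
    """Inverse of :func:`write_grid_stack` (NetCDF file or TIFF directory)."""
    path = Path(path)
    if path.is_file() and path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            data = ds["value"].to_numpy().astype(np.float64)
            years = ds["year"].to_numpy().astype(np.int64)
            nodata = float(ds.attrs.get("nodata", _NODATA))
            gt = ds.attrs.get("geotransform")
        mask = ~np.any(data == nodata, axis=0)
        data = data.copy()
        data[:, ~mask] = np.nan
        return GridStack(years, data, mask,
                         tuple(gt) if gt is not None else None)
    if path.is_dir():
        files = sorted(path.glob("*.tif"))
        if not files:
            raise ValidationError(f"{path}: no .tif files found")
        years, layers = [], []
        for f in files:
            m = re.search(r"(\d{4})", f.stem)
            if not m:
                raise ValidationError(f"{f.name}: no parseable year in filename")
            years.append(int(m.group(1)))
            layers.append(tifffile.imread(f).astype(np.float64))
        shapes = {layer.shape for layer in layers}
        if len(shapes) > 1:
            raise ValidationError(f"inconsistent raster shapes across years: {shapes}")
        years_arr = np.array(years)
        gaps = [
            y
            for y0, y1 in zip(sorted(years)[:-1], sorted(years)[1:])
            for y in range(y0 + 1, y1)
        ]
        if gaps:
            raise ValidationError(f"{path}: missing years {gaps}")
        order = np.argsort(years_arr)
        data = np.stack([layers[i] for i in order])
        mask = ~np.any(data == _NODATA, axis=0)
        data[:, ~mask] = np.nan
        return GridStack(years_arr[order], data, mask)
    raise ValidationError(f"{path}: not a .nc file or a directory")


# ---------------------------------------------------------------------------
# report tables

_FOOTNOTE = (
    "# * Significant at the 0.05 level; ** Significant at the 0.01 level\n"
)


def _starred(value: float, stars: str, ndigits: int = 3) -> str:
    return f"{value:.{ndigits}f}{stars}"


def write_trend_report(
    results: Mapping[str, Mapping[tuple[int, int], "TrendResult"]],
    path: str | Path,
) -> None:
    """Starred per-decade trend table: indicator rows x window columns."""
    from .trend import TrendResult  # noqa: F401 (type reference)

    windows: list[tuple[int, int]] = []
    for per_window in results.values():
        for w in per_window:
            if w not in windows:
                windows.append(w)
    rows = []
    for indicator, per_window in results.items():
        row: dict[str, str] = {"Indicator": indicator}
        for w in windows:
            key = f"{w[0]}-{w[1]}"
            res = per_window.get(w)
            row[key] = "" if res is None else _starred(res.slope_per_decade, res.stars)
        rows.append(row)
    columns = ["Indicator"] + [f"{w[0]}-{w[1]}" for w in windows]
    _write_with_footnote(pd.DataFrame(rows, columns=columns), path)


def write_pcorr_report(
    results: Mapping[tuple[int, int], Sequence["PartialCorrResult"]],
    path: str | Path,
) -> None:
    """Partial-correlation grid: covariate rows x window columns, starred."""
    from .pcorr import PartialCorrResult  # noqa: F401

    windows = list(results)
    covariates: list[str] = []
    for rs in results.values():
        for r in rs:
            if r.covariate not in covariates:
                covariates.append(r.covariate)
    rows = []
    for cov in covariates:
        row: dict[str, str] = {"Covariate": cov}
        for w in windows:
            match = [r for r in results[w] if r.covariate == cov]
            row[f"{w[0]}-{w[1]}"] = (
                _starred(match[0].r_partial, match[0].stars) if match else ""
            )
        rows.append(row)
    columns = ["Covariate"] + [f"{w[0]}-{w[1]}" for w in windows]
    _write_with_footnote(pd.DataFrame(rows, columns=columns), path)


def write_forecast_report(table: pd.DataFrame, path: str | Path) -> None:
    """Forecast accuracy table: Year, measured, predicted, difference,
    similarity (%)."""
    required = {"year", "measured", "predicted", "difference", "similarity_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"forecast table missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "Year": table["year"],
            "Exited value": table["measured"],
            "Predictive value": table["predicted"].round(4),
            "Difference": table["difference"].round(4),
            "Similarity (%)": table["similarity_pct"].map(lambda v: f"{v:.2f}%"),
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        out.to_csv(fh, index=False)


def write_report(results, path: str | Path, style: str) -> None:
    """Dispatch on report style: 'trend', 'pcorr' or 'forecast'."""
    writers = {
        "trend": write_trend_report,
        "pcorr": write_pcorr_report,
        "forecast": write_forecast_report,
    }
    if style not in writers:
        raise ValidationError(f"unknown report style {style!r}")
    try:
        writers[style](results, path)
    except (AttributeError, KeyError, TypeError) as exc:
        raise ValidationError(
            f"results do not match report style {style!r}: {exc}"
        ) from exc


def _write_with_footnote(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_FOOTNOTE)
        df.to_csv(fh, index=False)
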