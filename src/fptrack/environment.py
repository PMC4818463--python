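"""Per-polygon environmental covariates with 16- and 32-day lag differences.

Dynamic rasters (NDVI and mNDWI 16-day composites, daily precipitation and
temperature) are averaged temporally over each polygon's occupancy window
first, then spatially over the polygon — and the same double average is
taken over the window back-shifted by the lag, so a lagged difference
measures how the resource changed between the pre-arrival period and the
occupation period.  Together with static elevation and the tagging site this
yields twelve predictors per utilisation-distribution polygon:

    NDVI_t,  dNDVI_16,  dNDVI_32,
    mNDWI_t, dmNDWI_16, dmNDWI_32,
    Precip_t, dPrecip_16, dPrecip_32,
    Temp, Elev, site
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import Polygon

from .utilization import UDPolygon

logger = logging.getLogger("fptrack")

PREDICTOR_COLUMNS = [
    "ndvi_t",
    "d_ndvi_16",
    "d_ndvi_32",
    "mndwi_t",
    "d_mndwi_16",
    "d_mndwi_32",
    "precip_t",
    "d_precip_16",
    "d_precip_32",
    "temp",
    "elev",
    "site",
]

BOUNDED_VARIABLES = {"ndvi", "mndwi"}  # spectral indices live in [-1, 1]


class CoverageError(ValueError):
    """A requested window or polygon is not covered by the raster series."""


@dataclass
class RasterSeries:
    """A [time, y, x] raster time series on a regular planar grid.

    ``step`` is the composite/window length: each slice at time ``t_k`` is
    valid over ``[t_k, t_k + step)``.
    """

    variable: str
    data: xr.DataArray  # dims: time, y, x (cell-centre coordinates, metres)

    def __post_init__(self) -> None:
        times = pd.to_datetime(self.data["time"].values)
        if len(times) > 1:
            steps = np.diff(times)
            if not (times.is_monotonic_increasing and (steps == steps[0]).all()):
                raise ValueError(f"{self.variable}: times must be strictly increasing and even")
        v = self.variable.lower()
        if v in BOUNDED_VARIABLES:
            vals = self.data.values
            if np.nanmax(vals) > 1 + 1e-9 or np.nanmin(vals) < -1 - 1e-9:
                raise ValueError(f"{self.variable}: values outside [-1, 1]")
        if v == "precip" and np.nanmin(self.data.values) < -1e-9:
            raise ValueError("precip: negative values")

    @property
    def step(self) -> pd.Timedelta:
        times = pd.to_datetime(self.data["time"].values)
        if len(times) > 1:
            return pd.Timedelta(times[1] - times[0])
        return pd.Timedelta(days=1)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(pd.to_datetime(self.data["time"].values))


@dataclass
class StaticRaster:
    """A single static [y, x] raster (e.g. elevation)."""

    variable: str
    data: xr.DataArray


def spectral_index(band_a: np.ndarray, band_b: np.ndarray, kind: str = "ndvi") -> np.ndarray:
    """Normalised-difference ratio (a - b) / (a + b), NaN where both are zero.

    ``kind='ndvi'`` reads (NIR, red); ``kind='mndwi'`` reads (green, MIR).
    """
    a = np.asarray(band_a, dtype=float)
    b = np.asarray(band_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("reflectance bands must be non-negative")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def temporal_mean(series: RasterSeries, t0: pd.Timestamp, t1: pd.Timestamp) -> xr.DataArray:
    """Mean over all slices whose validity interval overlaps ``[t0, t1]``.

    Composites are unweighted; at least one slice must overlap or a
    :class:`CoverageError` names the variable.
    """
    if t0 > t1:
        raise ValueError("window start after end")
    times = series.times
    step = series.step
    # a slice [tk, tk+step) overlaps [t0, t1] iff tk <= t1 and tk + step > t0
    mask = (times <= t1) & ((times + step) > t0)
    if not mask.any():
        raise CoverageError(
            f"{series.variable}: window [{t0}, {t1}] outside series coverage "
            f"[{times[0]}, {times[-1] + step})"
        )
    return series.data.isel(time=np.flatnonzero(mask)).mean(dim="time")


def zonal_mean(raster: xr.DataArray, polygon: Polygon) -> float:
    """Mean over cells whose centre lies inside (or on) the polygon.

    Falls back to the nearest cell's value when the polygon is smaller than a
    cell; raises :class:`CoverageError` when the polygon misses the raster
    extent entirely.
    """
    x = raster["x"].values
    y = raster["y"].values
    minx, miny, maxx, maxy = polygon.bounds
    half = abs(float(x[1] - x[0])) / 2 if len(x) > 1 else np.inf
    if maxx < x.min() - half or minx > x.max() + half or maxy < y.min() - half or miny > y.max() + half:
        raise CoverageError("polygon entirely outside raster extent")
    ix = np.flatnonzero((x >= minx - half) & (x <= maxx + half))
    iy = np.flatnonzero((y >= miny - half) & (y <= maxy + half))
    if ix.size and iy.size:
        xx, yy = np.meshgrid(x[ix], y[iy])
        pts = shapely.points(xx.ravel(), yy.ravel())
        inside = shapely.covers(polygon, pts)
        if inside.any():
            vals = raster.values[np.ix_(iy, ix)].ravel()[inside]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                return float(vals.mean())
    # small-polygon guard: nearest cell to the centroid
    cx, cy = polygon.centroid.x, polygon.centroid.y
    jx = int(np.argmin(np.abs(x - cx)))
    jy = int(np.argmin(np.abs(y - cy)))
    val = float(raster.values[jy, jx])
    if not np.isfinite(val):
        raise CoverageError("no finite raster cells under polygon")
    return val


def lagged_difference(
    series: RasterSeries,
    t0: pd.Timestamp,
    t1: pd.Timestamp,
    lag: pd.Timedelta,
    polygon: Polygon,
) -> float:
    """Change in the polygon's double-averaged value between the occupancy
    window and the same window back-shifted by ``lag``:

        delta = mean(window) - mean(window - lag)

    Both windows must be covered by the series.
    """
    current = zonal_mean(temporal_mean(series, t0, t1), polygon)
    past = zonal_mean(temporal_mean(series, t0 - lag, t1 - lag), polygon)
    return current - past


def build_covariate_table(
    polygons: Sequence[UDPolygon],
    ndvi: RasterSeries,
    mndwi: RasterSeries,
    precip: RasterSeries,
    temp: RasterSeries,
    elevation: StaticRaster,
    sites: Mapping[str, str],
    bird_of_track: Mapping[str, str] | None = None,
    lags: tuple[int, int] = (16, 32),
) -> pd.DataFrame:
    """One covariate record per polygon: 12 predictors, log response, bird id.

    ``sites`` maps bird_id -> site code.  Polygons whose occupancy or lagged
    windows are not covered by a series are dropped (logged), matching the
    coverage rule for record inclusion.
    """
    lag_a, lag_b = (pd.Timedelta(days=d) for d in lags)
    records = []
    for p in polygons:
        bird = bird_of_track.get(p.track_label) if bird_of_track else p.track_label
        if bird is None or bird not in sites:
            raise KeyError(f"site mapping missing bird {bird!r} (track {p.track_label})")
        t0 = p.t_start.tz_localize(None) if p.t_start.tzinfo else p.t_start
        t1 = p.t_end.tz_localize(None) if p.t_end.tzinfo else p.t_end
        try:
            rec = {
                "polygon_id": p.polygon_id,
                "bird_id": bird,
                "site": sites[bird],
                "mfpt_rmax_h": p.mfpt_rmax_h,
                "log_mfpt": float(np.log(p.mfpt_rmax_h)),
                "ndvi_t": zonal_mean(temporal_mean(ndvi, t0, t1), p.geometry),
                "d_ndvi_16": lagged_difference(ndvi, t0, t1, lag_a, p.geometry),
                "d_ndvi_32": lagged_difference(ndvi, t0, t1, lag_b, p.geometry),
                "mndwi_t": zonal_mean(temporal_mean(mndwi, t0, t1), p.geometry),
                "d_mndwi_16": lagged_difference(mndwi, t0, t1, lag_a, p.geometry),
                "d_mndwi_32": lagged_difference(mndwi, t0, t1, lag_b, p.geometry),
                "precip_t": zonal_mean(temporal_mean(precip, t0, t1), p.geometry),
                "d_precip_16": lagged_difference(precip, t0, t1, lag_a, p.geometry),
                "d_precip_32": lagged_difference(precip, t0, t1, lag_b, p.geometry),
                "temp": zonal_mean(temporal_mean(temp, t0, t1), p.geometry),
                "elev": zonal_mean(elevation.data, p.geometry),
            }
        except CoverageError as err:
            logger.info("polygon %s: dropped (%s)", p.polygon_id, err)
            continue
        records.append(rec)
    return pd.DataFrame.from_records(records)


def rasters_to_netcdf(series: Sequence[RasterSeries], static: StaticRaster, path) -> None:
    """Write the raster bundle as a CF-style NetCDF (time, y, x)."""
    ds = xr.Dataset({s.variable: s.data for s in series})
    ds[static.variable] = static.data
    ds.to_netcdf(path)
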