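"""Ingest, clean, split, and project GPS telemetry into analysis-ready tracks.

A *track* is the ordered sequence of GPS fixes for one tracking bout of one
bird.  Raw telemetry arrives as CSV (Movebank-style column names are accepted
via a mapping); tracks with transmission gaps longer than one week are split
into separate bouts, labelled with the suffixes ``a``, ``b``, ``c`` ... in
temporal order, and bouts shorter than 90 days are excluded from analysis.

All downstream computations (first-passage time, kernel densities) need
metric coordinates, so each track can be projected into a local azimuthal
equidistant frame centred on its mean position, which is distance-true near
the centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fptrack")

EARTH_RADIUS_M = 6_371_000.0

#: default column mapping: canonical name -> accepted aliases (first match wins)
DEFAULT_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "bird_id": ("bird_id", "individual-local-identifier", "id", "animal_id", "transmitter"),
    "timestamp": ("timestamp", "datetime", "date_time", "study-local-timestamp"),
    "lon": ("lon", "longitude", "location-long", "x_deg"),
    "lat": ("lat", "latitude", "location-lat", "y_deg"),
    "x": ("x", "x_m", "easting"),
    "y": ("y", "y_m", "northing"),
    "species": ("species", "individual-taxon-canonical-name"),
    "site": ("site", "tagging_site", "study-site"),
    "track_label": ("track_label",),
}


class TelemetryError(ValueError):
    """Raised for malformed telemetry input (bad rows, empty files, bad coords)."""


@dataclass(frozen=True)
class Fix:
    """A single GPS relocation."""

    bird_id: str
    track_label: str
    timestamp: pd.Timestamp
    x: float
    y: float
    lon: float | None = None
    lat: float | None = None


@dataclass
class Track:
    """Ordered GPS fixes for one tracking bout of one bird.

    ``fixes`` is a DataFrame with columns ``timestamp`` (tz-aware UTC),
    ``x``/``y`` (planar metres once projected) and optionally ``lon``/``lat``.
    """

    bird_id: str
    track_label: str
    fixes: pd.DataFrame
    species: str | None = None
    site: str | None = None
    is_planar: bool = False
    projection_origin: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if not ts.is_monotonic_increasing:
            raise TelemetryError(f"track {self.track_label}: timestamps not sorted")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def duration_days(self) -> float:
        ts = self.fixes["timestamp"]
        return (ts.iloc[-1] - ts.iloc[0]) / pd.Timedelta(days=1)

    @property
    def timestamps(self) -> pd.Series:
        return self.fixes["timestamp"]

    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    def times_seconds(self) -> np.ndarray:
        """Seconds elapsed since the first fix."""
        ts = self.fixes["timestamp"]
        return ((ts - ts.iloc[0]) / pd.Timedelta(seconds=1)).to_numpy(dtype=float)


def _resolve_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> dict[str, str]:
    resolved: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for canon, aliases in DEFAULT_COLUMNS.items():
        if column_map and canon in column_map:
            if column_map[canon] in df.columns:
                resolved[canon] = column_map[canon]
            continue
        for alias in aliases:
            if alias.lower() in lower:
                resolved[canon] = lower[alias.lower()]
                break
    return resolved


def parse_tracks(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[Track]:
    """Read a telemetry CSV and return one :class:`Track` per (bird, label).

    Rows are sorted by time within each track; duplicate timestamps within a
    bird keep the first occurrence (the rest are logged and dropped).  Naive
    timestamps are assumed UTC with a warning.

    Raises
    ------
    TelemetryError
        for an empty file, missing required columns, or an unparseable
        timestamp (the error names the offending row number).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise TelemetryError(f"{path}: empty telemetry file")
    cols = _resolve_columns(df, column_map)
    missing = {"bird_id", "timestamp"} - set(cols)
    if missing:
        raise TelemetryError(f"{path}: missing required columns {sorted(missing)}")
    if "lon" not in cols and "x" not in cols:
        raise TelemetryError(f"{path}: need lon/lat or x/y coordinate columns")

    ts = pd.to_datetime(df[cols["timestamp"]], errors="coerce", utc=False, format="mixed")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise TelemetryError(
            f"{path}: unparseable timestamp at row {row + 2} "
            f"(value {df[cols['timestamp']].iloc[row]!r})"
        )
    if ts.dt.tz is None:
        logger.warning("%s: naive timestamps assumed UTC", path.name)
        ts = ts.dt.tz_localize("UTC")
    else:
        ts = ts.dt.tz_convert("UTC")

    out = pd.DataFrame({"bird_id": df[cols["bird_id"]].astype(str), "timestamp": ts})
    has_lonlat = "lon" in cols and "lat" in cols
    if has_lonlat:
        out["lon"] = pd.to_numeric(df[cols["lon"]])
        out["lat"] = pd.to_numeric(df[cols["lat"]])
    planar_in = "x" in cols and "y" in cols
    if planar_in:
        out["x"] = pd.to_numeric(df[cols["x"]])
        out["y"] = pd.to_numeric(df[cols["y"]])
    for extra in ("species", "site"):
        if extra in cols:
            out[extra] = df[cols[extra]].astype(str)
    label_col = cols.get("track_label")
    out["track_label"] = df[label_col].astype(str) if label_col else out["bird_id"]

    tracks: list[Track] = []
    for (bird, label), grp in out.groupby(["bird_id", "track_label"], sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        dup = grp["timestamp"].duplicated(keep="first")
        if dup.any():
            logger.info("track %s: dropped %d duplicate-timestamp fixes", label, int(dup.sum()))
            grp = grp[~dup]
        grp = grp.reset_index(drop=True)
        tracks.append(
            Track(
                bird_id=str(bird),
                track_label=str(label),
                fixes=grp.drop(columns=["bird_id", "species", "site"], errors="ignore"),
                species=str(grp["species"].iloc[0]) if "species" in grp else None,
                site=str(grp["site"].iloc[0]) if "site" in grp else None,
                is_planar=planar_in and not has_lonlat,
            )
        )
    return tracks


def _suffixes() -> Iterable[str]:
    import itertools
    import string

    for n in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=n):
            yield "".join(combo)


def split_on_gaps(track: Track, max_gap: pd.Timedelta = pd.Timedelta(days=7)) -> list[Track]:
    """Split a track wherever the interval between consecutive fixes exceeds
    ``max_gap`` (strictly greater; exactly one week does not split).

    The first bout keeps the original label; subsequent bouts are suffixed
    ``a``, ``b``, ``c`` ... in temporal order.
    """
    ts = track.fixes["timestamp"]
    gaps = ts.diff().iloc[1:]
    cut_after = np.flatnonzero((gaps > max_gap).to_numpy())  # index of fix before the gap
    if cut_after.size == 0:
        return [track]
    bounds = [0, *(cut_after + 1), len(ts)]
    pieces: list[Track] = []
    suffix = _suffixes()
    for k in range(len(bounds) - 1):
        sub = track.fixes.iloc[bounds[k] : bounds[k + 1]].reset_index(drop=True)
        label = track.track_label if k == 0 else track.track_label + next(suffix)
        pieces.append(replace(track, track_label=label, fixes=sub))
    return pieces


def filter_min_duration(tracks: Sequence[Track], min_days: float = 90.0) -> list[Track]:
    """Drop tracks shorter than ``min_days`` (strictly less than; 90.0 days is
    retained).  Removals are logged per track."""
    kept: list[Track] = []
    for t in tracks:
        d = t.duration_days if t.n_fixes >= 2 else 0.0
        if d < min_days:
            logger.info("track %s: excluded, duration %.1f d < %.0f d", t.track_label, d, min_days)
        else:
            kept.append(t)
    return kept


# --- local azimuthal equidistant projection -------------------------------
# Distance-true from the centre point; adequate for FPT radii (<= 10 km)
# over tracks spanning hundreds of km.


def geographic_to_planar(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward azimuthal equidistant projection on the sphere (metres)."""
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    # k = c / sin(c), with the removable singularity at the centre
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def planar_to_geographic(
    x: np.ndarray, y: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`geographic_to_planar`."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    rho = np.hypot(x, y)
    safe_rho = np.where(rho > 1e-9, rho, 1.0)
    c = rho / EARTH_RADIUS_M
    sin_c, cos_c = np.sin(c), np.cos(c)
    phi = np.arcsin(np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_rho, -1, 1))
    lam = lam0 + np.arctan2(x * sin_c, safe_rho * cos_c * np.cos(phi0) - y * sin_c * np.sin(phi0))
    phi = np.where(rho > 1e-9, phi, phi0)
    lam = np.where(rho > 1e-9, lam, lam0)
    return np.degrees(lam), np.degrees(phi)


def to_planar(track: Track, origin: tuple[float, float] | None = None) -> Track:
    """Project a track's lon/lat into planar metres.

    The default frame is azimuthal equidistant centred on the track's mean
    coordinate; pass ``origin=(lon0, lat0)`` to share a frame across tracks.
    Tracks already flagged planar are returned unchanged.
    """
    if track.is_planar:
        return track
    if "lon" not in track.fixes or "lat" not in track.fixes:
        raise TelemetryError(f"track {track.track_label}: no lon/lat to project")
    lon = track.fixes["lon"].to_numpy(dtype=float)
    lat = track.fixes["lat"].to_numpy(dtype=float)
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise TelemetryError(f"track {track.track_label}: coordinates outside valid lon/lat range")
    lon0, lat0 = origin if origin is not None else (float(lon.mean()), float(lat.mean()))
    x, y = geographic_to_planar(lon, lat, lon0, lat0)
    fixes = track.fixes.copy()
    fixes["x"], fixes["y"] = x, y
    return replace(track, fixes=fixes, is_planar=True, projection_origin=(lon0, lat0))


def write_tracks(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks back to CSV (same dialect, plus ``track_label``)."""
    frames = []
    for t in tracks:
        df = t.fixes.copy()
        df.insert(0, "bird_id", t.bird_id)
        df["track_label"] = t.track_label
        if t.species is not None:
            df["species"] = t.species
        if t.site is not None:
            df["site"] = t.site
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def prepare_tracks(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    max_gap: pd.Timedelta = pd.Timedelta(days=7),
    min_days: float = 90.0,
    origin: tuple[float, float] | None = None,
) -> list[Track]:
    """parse -> split on gaps -> duration filter -> project, in one call."""
    tracks = parse_tracks(path, column_map)
    split: list[Track] = []
    for t in tracks:
        split.extend(split_on_gaps(t, max_gap=max_gap))
    kept = filter_min_duration(split, min_days=min_days)
    return [to_planar(t, origin=origin) for t in kept]
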