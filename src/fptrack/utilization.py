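"""Per-segment utilisation distributions and their isopleth polygons.

Each movement segment's fixes are turned into a utilisation distribution
(UD) with a bivariate Gaussian kernel density estimate on a regular grid;
the smallest density superlevel set holding a target fraction of the mass
(default 95%) is vectorised into polygons.  Each polygon is a sampling
unit: it carries the mean FPT at the ARS scale over its member fixes
(mFPT_Rmax), its planar area, and its occupancy window.

The kernel is a plain product Gaussian with per-axis Silverman bandwidths;
the kernel interface is a single function so that movement-informed kernels
can be slotted in without touching the polygon logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from skimage import measure

from .fpt import FPTProfile

logger = logging.getLogger("fptrack")

DEFAULT_ISOPLETH = 0.95
DEFAULT_CELL_M = 100.0


@dataclass
class DensityGrid:
    """Normalised kernel density on a regular planar grid."""

    x: np.ndarray  # cell-centre x coordinates, shape [nx]
    y: np.ndarray  # cell-centre y coordinates, shape [ny]
    density: np.ndarray  # shape [ny, nx], integrates to 1
    cell: float

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class UDPolygon:
    """One utilisation-distribution polygon — a sampling unit."""

    track_label: str
    segment_id: int
    polygon_id: str
    geometry: Polygon
    area_km2: float
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    n_fixes: int
    mfpt_rmax_h: float

    @property
    def occupancy_days(self) -> float:
        return (self.t_end - self.t_start) / pd.Timedelta(days=1)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's reference rule for one axis (metres)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return 1.06 * sd * n ** (-1 / 5) if sd > 0 else 0.0


def estimate_density(
    xy: np.ndarray,
    bandwidth: float | tuple[float, float] | None = None,
    cell: float = DEFAULT_CELL_M,
    pad_bandwidths: float = 3.5,
) -> DensityGrid:
    """Bivariate Gaussian KDE of one segment's fixes on a padded grid.

    The grid extends at least three bandwidths beyond the fixes' bounding box
    and the returned density integrates to one.  Degenerate inputs (all fixes
    identical) collapse to a single-cell point mass with a warning.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be an [n, 2] array")
    if len(xy) < 5:
        raise ValueError("estimate_density needs >= 5 fixes")
    if bandwidth is None:
        hx = silverman_bandwidth(xy[:, 0])
        hy = silverman_bandwidth(xy[:, 1])
    elif np.isscalar(bandwidth):
        hx = hy = float(bandwidth)
    else:
        hx, hy = (float(b) for b in bandwidth)
    if hx <= 0 or hy <= 0:
        logger.warning("degenerate fixes: zero spread; returning single-cell mass")
        gx = np.array([float(xy[:, 0].mean())])
        gy = np.array([float(xy[:, 1].mean())])
        return DensityGrid(x=gx, y=gy, density=np.array([[1.0 / cell**2]]), cell=cell)
    pad_x, pad_y = pad_bandwidths * hx, pad_bandwidths * hy
    gx = np.arange(xy[:, 0].min() - pad_x, xy[:, 0].max() + pad_x + cell, cell)
    gy = np.arange(xy[:, 1].min() - pad_y, xy[:, 1].max() + pad_y + cell, cell)
    # separable Gaussian kernel: density = ky^T kx / (2 pi hx hy n)
    kx = np.exp(-0.5 * ((gx[None, :] - xy[:, 0][:, None]) / hx) ** 2)
    ky = np.exp(-0.5 * ((gy[None, :] - xy[:, 1][:, None]) / hy) ** 2)
    dens = ky.T @ kx / (2 * np.pi * hx * hy * len(xy))
    mass = dens.sum() * cell * cell
    dens /= mass  # renormalise for truncation at the grid edge
    return DensityGrid(x=gx, y=gy, density=dens, cell=cell)


def _superlevel_threshold(grid: DensityGrid, level: float) -> float:
    """Density value whose superlevel set is the smallest holding >= level mass."""
    flat = np.sort(grid.density.ravel())[::-1]
    csum = np.cumsum(flat) * grid.cell_area
    k = int(np.searchsorted(csum, level))
    k = min(k, len(flat) - 1)
    return float(flat[k])


def isopleth_polygons(grid: DensityGrid, level: float = DEFAULT_ISOPLETH) -> list[Polygon]:
    """Vectorise the ``level`` isopleth of a normalised UD into polygons.

    Contours are traced by marching squares on the zero-padded density, so
    every ring closes; rings nested inside another ring become holes.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"isopleth level must be in (0, 1), got {level}")
    if grid.density.size == 1:
        half = grid.cell / 2
        x0, y0 = grid.x[0], grid.y[0]
        return [
            Polygon(
                [(x0 - half, y0 - half), (x0 + half, y0 - half), (x0 + half, y0 + half), (x0 - half, y0 + half)]
            )
        ]
    thr = _superlevel_threshold(grid, level)
    padded = np.pad(grid.density, 1, constant_values=0.0)
    contours = measure.find_contours(padded, thr)
    rings = []
    for c in contours:
        # contour coords are (row, col) in the padded grid; map to x/y
        xs = np.interp(c[:, 1] - 1, np.arange(len(grid.x)), grid.x)
        ys = np.interp(c[:, 0] - 1, np.arange(len(grid.y)), grid.y)
        if len(xs) >= 4:
            ring = Polygon(np.column_stack([xs, ys]))
            if ring.is_valid and ring.area > 0:
                rings.append(ring)
    if not rings:
        return []
    # classify rings: exteriors vs holes by containment depth
    polys: list[Polygon] = []
    rings_sorted = sorted(rings, key=lambda r: r.area, reverse=True)
    assigned_holes: dict[int, list] = {}
    exterior_idx: list[int] = []
    for i, ring in enumerate(rings_sorted):
        parents = [
            j
            for j in range(len(rings_sorted))
            if j != i
            and rings_sorted[j].area > ring.area
            and rings_sorted[j].contains(ring.representative_point())
        ]
        if len(parents) % 2 == 0:
            exterior_idx.append(i)
            assigned_holes[i] = []
        else:
            # innermost parent gets the hole
            parent = min(parents, key=lambda j: rings_sorted[j].area)
            assigned_holes.setdefault(parent, []).append(ring)
    for i in exterior_idx:
        ext = rings_sorted[i]
        holes = [list(h.exterior.coords) for h in assigned_holes.get(i, [])]
        poly = Polygon(list(ext.exterior.coords), holes)
        if not poly.is_valid:
            poly = poly.buffer(0)
        for part in getattr(poly, "geoms", [poly]):
            if part.area > 0:
                polys.append(part)
    return polys


def polygon_metrics(
    polygon: Polygon,
    segment_fixes: pd.DataFrame,
    profile: FPTProfile,
    r_max: float,
    fix_indices: np.ndarray,
    track_label: str,
    segment_id: int,
    polygon_id: str,
) -> UDPolygon | None:
    """Assemble a :class:`UDPolygon` from one isopleth polygon.

    Membership is point-in-polygon with boundary points counted inside;
    mFPT_Rmax is the mean defined FPT at r_max over member fixes.  Polygons
    with no member fixes or no defined FPT are dropped (None, logged).
    """
    pts = shapely.points(segment_fixes["x"].to_numpy(), segment_fixes["y"].to_numpy())
    member = shapely.covers(polygon, pts)
    if not member.any():
        logger.info("polygon %s: no member fixes, dropped", polygon_id)
        return None
    fpt_col = profile.fpt_at(r_max)[fix_indices[member]]
    fpt_col = fpt_col[np.isfinite(fpt_col)]
    if fpt_col.size == 0:
        logger.info("polygon %s: no defined FPT among members, dropped", polygon_id)
        return None
    ts = segment_fixes.loc[member, "timestamp"]
    return UDPolygon(
        track_label=track_label,
        segment_id=segment_id,
        polygon_id=polygon_id,
        geometry=polygon,
        area_km2=polygon.area / 1e6,
        t_start=ts.min(),
        t_end=ts.max(),
        n_fixes=int(member.sum()),
        mfpt_rmax_h=float(fpt_col.mean()),
    )


def build_ud_polygons(
    track_fixes: pd.DataFrame,
    segment_id: np.ndarray,
    profile: FPTProfile,
    r_max: float,
    level: float = DEFAULT_ISOPLETH,
    bandwidth: float | None = None,
    cell: float = DEFAULT_CELL_M,
) -> list[UDPolygon]:
    """UD polygons for every segment of one track."""
    out: list[UDPolygon] = []
    for seg in np.unique(segment_id):
        mask = segment_id == seg
        if mask.sum() < 5:
            logger.info(
                "track %s segment %d: %d fixes < 5, no UD", profile.track_label, seg, mask.sum()
            )
            continue
        seg_fixes = track_fixes.loc[mask].reset_index(drop=True)
        grid = estimate_density(seg_fixes[["x", "y"]].to_numpy(), bandwidth=bandwidth, cell=cell)
        polys = isopleth_polygons(grid, level=level)
        fix_idx = np.flatnonzero(mask)
        for p_i, poly in enumerate(polys):
            rec = polygon_metrics(
                poly,
                seg_fixes,
                profile,
                r_max,
                fix_idx,
                profile.track_label,
                int(seg),
                f"{profile.track_label}_s{int(seg)}_p{p_i}",
            )
            if rec is not None:
                out.append(rec)
    return out


def polygons_to_frame(polygons: list[UDPolygon]) -> pd.DataFrame:
    """Tabular metrics view of UD polygons (geometry omitted)."""
    return pd.DataFrame(
        {
            "polygon_id": [p.polygon_id for p in polygons],
            "track_label": [p.track_label for p in polygons],
            "segment_id": [p.segment_id for p in polygons],
            "area_km2": [p.area_km2 for p in polygons],
            "t_start": [p.t_start for p in polygons],
            "t_end": [p.t_end for p in polygons],
            "n_fixes": [p.n_fixes for p in polygons],
            "mfpt_rmax_h": [p.mfpt_rmax_h for p in polygons],
            "occupancy_days": [p.occupancy_days for p in polygons],
        }
    )


def polygons_to_geojson(polygons: list[UDPolygon], path, projection_origin=None) -> None:
    """Write polygons as GeoJSON in planar coordinates (projection recorded
    in the feature properties)."""
    import json

    features = []
    for p in polygons:
        features.append(
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(p.geometry),
                "properties": {
                    "polygon_id": p.polygon_id,
                    "track_label": p.track_label,
                    "segment_id": p.segment_id,
                    "area_km2": p.area_km2,
                    "mfpt_rmax_h": p.mfpt_rmax_h,
                    "t_start": str(p.t_start),
                    "t_end": str(p.t_end),
                    "n_fixes": p.n_fixes,
                    "crs_note": "local planar metres",
                    "projection_origin_lonlat": projection_origin,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
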