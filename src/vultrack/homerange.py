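"""Kernel-density home ranges and their comparison.

The utilization distribution is an isotropic Gaussian KDE evaluated on a
regular equal-area grid (km cells). Points are binned to cell centres and
smoothed with a separable Gaussian — numerically equivalent to direct
kernel evaluation up to half-cell binning error, and fast enough for
multi-year 30-min tracks. The `level` isopleth is the smallest set of
cells whose probability mass reaches `level`; its area in km² is the
home-range estimate and its density-weighted centre of mass the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import EqualAreaProjection, GeoPoint, haversine_km
from .io import Trajectory


class DegenerateInputError(ValueError):
    """All points identical (or too few distinct) — no density to estimate."""


@dataclass
class KDEEstimate:
    """A fitted utilization distribution with its isopleth summary.

    ``density`` (shape ny × nx, row iy / col ix) integrates to exactly 1
    over the grid: density is renormalised after smoothing so that edge
    truncation at the padded boundary cannot leak mass. ``x0``/``y0`` are
    the centre of cell (0, 0) in projected km.
    """

    projection: EqualAreaProjection
    x0: float
    y0: float
    cell_km: float
    density: np.ndarray
    bandwidth_km: float
    level: float
    threshold: float
    mask: np.ndarray
    area_km2: float
    centroid: GeoPoint
    n_points: int
    points_lon: np.ndarray
    points_lat: np.ndarray

    @property
    def center(self) -> GeoPoint:
        return self.projection.center

    def mass_inside(self) -> float:
        """Probability mass enclosed by the isopleth mask."""
        return float(self.density[self.mask].sum() * self.cell_km ** 2)

    def isopleth_polygons(self):
        """Isopleth outline(s) as shapely polygons in lon/lat (WGS84)."""
        from shapely import union_all
        from shapely.geometry import box
        from shapely.ops import transform

        half = self.cell_km / 2.0
        iy, ix = np.nonzero(self.mask)
        boxes = [box(self.x0 + i * self.cell_km - half, self.y0 + j * self.cell_km - half,
                     self.x0 + i * self.cell_km + half, self.y0 + j * self.cell_km + half)
                 for j, i in zip(iy, ix)]
        merged = union_all(boxes)

        def to_lonlat(x, y):
            return self.projection.inverse(np.asarray(x), np.asarray(y))

        return transform(to_lonlat, merged)


def silverman_bandwidth_km(x: np.ndarray, y: np.ndarray) -> float:
    """Reference bandwidth for a 2-D isotropic Gaussian kernel:
    h = sigma * n^(-1/6), with sigma the root mean of the two marginal
    variances of the projected coordinates (Silverman's rule, d = 2)."""
    n = x.size
    sigma = np.sqrt(0.5 * (np.var(x, ddof=1) + np.var(y, ddof=1)))
    return float(sigma * n ** (-1.0 / 6.0))


def fit_kde(lon, lat, bandwidth: float | str = "reference", cell_km: float = 5.0,
            level: float = 0.95, center: GeoPoint | None = None,
            pad_bandwidths: float = 3.0) -> KDEEstimate:
    """Fit the gridded utilization distribution of a point cloud.

    Parameters
    ----------
    lon, lat : array-like, decimal degrees (≥10 points required)
    bandwidth : kernel SD in km, or "reference" for Silverman's rule on the
        projected coordinates
    cell_km : grid cell edge, km
    level : isopleth probability (0.95 by default)
    center : projection centre; defaults to the cloud's geographic centroid
    pad_bandwidths : grid margin beyond the data extent, in bandwidths
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 10:
        raise ValueError(f"need at least 10 points to fit a KDE, got {lon.size}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")

    proj = (EqualAreaProjection(center) if center is not None
            else EqualAreaProjection.for_points(lon, lat))
    x, y = proj.forward(lon, lat)
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        raise DegenerateInputError("all points identical; KDE undefined")

    if isinstance(bandwidth, str):
        if bandwidth != "reference":
            raise ValueError(f"unknown bandwidth rule: {bandwidth!r}")
        h = silverman_bandwidth_km(x, y)
    else:
        h = float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")

    pad = pad_bandwidths * h
    return _fit_on_grid(proj, x, y, lon, lat, h, cell_km, level,
                        x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)


def _fit_on_grid(proj, x, y, lon, lat, h, cell_km, level,
                 xmin, xmax, ymin, ymax) -> KDEEstimate:
    nx = max(int(np.ceil((xmax - xmin) / cell_km)), 4)
    ny = max(int(np.ceil((ymax - ymin) / cell_km)), 4)
    x_edges = xmin + np.arange(nx + 1) * cell_km
    y_edges = ymin + np.arange(ny + 1) * cell_km

    counts, _, _ = np.histogram2d(y, x, bins=[y_edges, x_edges])
    density = gaussian_filter(counts, sigma=h / cell_km, mode="constant", truncate=6.0)
    total = density.sum() * cell_km ** 2
    if total <= 0:
        raise DegenerateInputError("no probability mass on the grid")
    density /= total    # integrates to exactly 1 on the grid

    threshold, mask = _isopleth(density, cell_km, level)
    area = float(mask.sum()) * cell_km ** 2

    w = np.where(mask, density, 0.0)
    wsum = w.sum()
    cx = x_edges[:-1] + cell_km / 2.0
    cy = y_edges[:-1] + cell_km / 2.0
    cx_mean = float((w.sum(axis=0) * cx).sum() / wsum)
    cy_mean = float((w.sum(axis=1) * cy).sum() / wsum)
    c_lon, c_lat = proj.inverse(cx_mean, cy_mean)

    return KDEEstimate(projection=proj, x0=float(cx[0]), y0=float(cy[0]),
                       cell_km=cell_km, density=density, bandwidth_km=h,
                       level=level, threshold=threshold, mask=mask, area_km2=area,
                       centroid=GeoPoint(float(c_lon), float(c_lat)),
                       n_points=int(x.size), points_lon=lon, points_lat=lat)


def _isopleth(density: np.ndarray, cell_km: float, level: float):
    """Largest density value t such that cells with density ≥ t hold mass
    ≥ level (the smallest region containing at least `level` mass)."""
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat) * cell_km ** 2
    k = int(np.searchsorted(cum, level, side="left"))
    k = min(k, flat.size - 1)
    threshold = float(flat[k])
    return threshold, density >= threshold


def isopleth_mask(est: KDEEstimate, level: float) -> np.ndarray:
    """Mask of the given isopleth level on an existing fit (nested in the
    fit's own mask whenever level ≤ est.level)."""
    _, mask = _isopleth(est.density, est.cell_km, level)
    return mask


@dataclass(frozen=True)
class OverlapResult:
    id_a: str
    id_b: str
    overlap_pct: float          # symmetric: mean of the two directed overlaps
    directed_a_pct: float       # area(A∩B) / area(A) × 100
    directed_b_pct: float       # area(A∩B) / area(B) × 100
    centroid_distance_km: float
    same_nucleus: bool | None = None


def _midpoint(a: GeoPoint, b: GeoPoint) -> GeoPoint:
    va = np.array([np.cos(np.radians(a.lat)) * np.cos(np.radians(a.lon)),
                   np.cos(np.radians(a.lat)) * np.sin(np.radians(a.lon)),
                   np.sin(np.radians(a.lat))])
    vb = np.array([np.cos(np.radians(b.lat)) * np.cos(np.radians(b.lon)),
                   np.cos(np.radians(b.lat)) * np.sin(np.radians(b.lon)),
                   np.sin(np.radians(b.lat))])
    v = va + vb
    lat = np.degrees(np.arctan2(v[2], np.hypot(v[0], v[1])))
    lon = np.degrees(np.arctan2(v[1], v[0]))
    return GeoPoint(float(lon), float(lat))


def _shared_lattice(a: KDEEstimate, b: KDEEstimate):
    """Refit both estimates on one lattice centred at the midpoint of their
    projection centres, preserving each fit's bandwidth and the finer cell."""
    center = _midpoint(a.center, b.center)
    proj = EqualAreaProjection(center)
    cell = min(a.cell_km, b.cell_km)
    xa, ya = proj.forward(a.points_lon, a.points_lat)
    xb, yb = proj.forward(b.points_lon, b.points_lat)
    pad_a, pad_b = 3.0 * a.bandwidth_km, 3.0 * b.bandwidth_km
    xmin = min(xa.min() - pad_a, xb.min() - pad_b)
    xmax = max(xa.max() + pad_a, xb.max() + pad_b)
    ymin = min(ya.min() - pad_a, yb.min() - pad_b)
    ymax = max(ya.max() + pad_a, yb.max() + pad_b)
    fa = _fit_on_grid(proj, xa, ya, a.points_lon, a.points_lat, a.bandwidth_km,
                      cell, a.level, xmin, xmax, ymin, ymax)
    fb = _fit_on_grid(proj, xb, yb, b.points_lon, b.points_lat, b.bandwidth_km,
                      cell, b.level, xmin, xmax, ymin, ymax)
    return fa, fb, cell


def overlap_pct(a: KDEEstimate, b: KDEEstimate) -> float:
    """Symmetric isopleth overlap in percent: the mean of
    area(A∩B)/area(A) and area(A∩B)/area(B), ×100, computed after
    re-gridding both fits onto a shared lattice."""
    return pairwise_overlap(a, b).overlap_pct


def pairwise_overlap(a: KDEEstimate, b: KDEEstimate,
                     id_a: str = "a", id_b: str = "b",
                     same_nucleus: bool | None = None) -> OverlapResult:
    """Full overlap record (symmetric and both directed percentages, plus
    the centroid distance)."""
    fa, fb, cell = _shared_lattice(a, b)
    inter = float(np.logical_and(fa.mask, fb.mask).sum()) * cell ** 2
    da = 100.0 * inter / fa.area_km2
    db = 100.0 * inter / fb.area_km2
    return OverlapResult(id_a, id_b, overlap_pct=0.5 * (da + db),
                         directed_a_pct=da, directed_b_pct=db,
                         centroid_distance_km=centroid_distance_km(a, b),
                         same_nucleus=same_nucleus)


def centroid_distance_km(a: KDEEstimate, b: KDEEstimate) -> float:
    """Great-circle distance between the density-weighted isopleth centroids."""
    return float(haversine_km(a.centroid.lon, a.centroid.lat,
                              b.centroid.lon, b.centroid.lat))


def monthly_kde(traj: Trajectory, core_polygons: dict[str, object] | None = None,
                min_fixes: int = 10, **kde_kwargs):
    """Per-calendar-month KDE for a resident's track.

    Returns ``(estimates, occupancy)``: a dict mapping ``pandas.Period``
    (month) to KDEEstimate for every month with at least ``min_fixes``
    fixes (others skipped), and a DataFrame with the monthly percentage of
    fixes inside each named core polygon (lon/lat shapely geometries) —
    the histogram companion to the seasonal two-core residency pattern.
    Note the union of monthly isopleths is not the all-data isopleth:
    monthly fits are separate distributions.
    """
    import shapely

    f = traj.fixes
    months = f["timestamp"].dt.to_period("M")
    estimates: dict[pd.Period, KDEEstimate] = {}
    occ_rows = []
    for month, sub in f.groupby(months):
        row: dict[str, object] = {"month": month, "n_fixes": len(sub)}
        if core_polygons:
            for name, poly in core_polygons.items():
                inside = shapely.contains_xy(poly, sub["lon"].to_numpy(),
                                             sub["lat"].to_numpy())
                row[f"pct_in_{name}"] = 100.0 * inside.mean()
        occ_rows.append(row)
        if len(sub) >= min_fixes:
            try:
                estimates[month] = fit_kde(sub["lon"], sub["lat"], **kde_kwargs)
            except DegenerateInputError:
                pass
    occupancy = pd.DataFrame(occ_rows)
    return estimates, occupancy
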