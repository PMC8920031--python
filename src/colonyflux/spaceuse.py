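"""Kernel utilization distributions of at-sea foraging locations.

At-sea fixes (decoded flight/water, >= 500 m from the colony) are
projected onto a local planar frame, smoothed with a bivariate Gaussian
kernel on a regular grid, and summarised as isopleth areas: the p-level
isopleth is the smallest set of highest-density cells holding at least
probability mass p.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .config import BEHAVIOURS
from .containers import GpsTrack, StatePath
from .features import NEAR_THRESHOLD_M, EARTH_RADIUS_M, haversine_distance

_AT_SEA = (BEHAVIOURS.index("flight"), BEHAVIOURS.index("water"))

DEFAULT_LEVELS = (0.50, 0.75, 0.85, 0.95)


def project_to_plane(lat, lon, colony: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection centred on the colony (metres).

    x is easting, y is northing; the colony maps to the origin.  Metre
    accurate at the sub-100 km scale of foraging trips.
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    lat0, lon0 = colony
    k = np.pi / 180.0 * EARTH_RADIUS_M
    x = (lon - lon0) * k * np.cos(np.radians(lat0))
    y = (lat - lat0) * k
    return x, y


def unproject_from_plane(x, y, colony: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_to_plane`."""
    lat0, lon0 = colony
    k = np.pi / 180.0 * EARTH_RADIUS_M
    lat = lat0 + np.asarray(y, float) / k
    lon = lon0 + np.asarray(x, float) / (k * np.cos(np.radians(lat0)))
    return lat, lon


def select_foraging_points(
    track: GpsTrack,
    path: StatePath,
    colony: tuple,
    window_s: float = 15.0,
) -> np.ndarray:
    """Planar coordinates of fixes in decoded at-sea behaviour, far from
    the colony.  Decoded water or flight stands in for area-restricted
    search; the 500 m exclusion removes colony-attendance fixes."""
    if len(track) == 0:
        return np.empty((0, 2))
    offset = (track.t0 - path.t0).total_seconds()
    t_on_path = track.t + offset
    grid = path.midpoints - window_s / 2.0
    widx = np.clip(np.searchsorted(grid, t_on_path, side="right") - 1, 0, len(path) - 1)
    at_sea = np.isin(path.states[widx], _AT_SEA) & ~path.missing[widx]
    dist = haversine_distance(track.lat, track.lon, colony[0], colony[1])
    keep = at_sea & (dist >= NEAR_THRESHOLD_M)
    if not keep.any():
        warnings.warn("no at-sea foraging fixes retained")
        return np.empty((0, 2))
    x, y = project_to_plane(track.lat[keep], track.lon[keep], colony)
    return np.column_stack([x, y])


@dataclass
class UdGrid:
    """Gridded utilization density (sums to 1 over the grid)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # (nx, ny) cell probability masses
    cell_m: float
    bandwidth_m: float

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_m / 1000.0) ** 2


@dataclass
class IsoplethSet:
    """Per-level isopleth polygons and areas (km^2)."""

    levels: tuple
    areas_km2: dict = field(default_factory=dict)
    masses: dict = field(default_factory=dict)
    polygons: dict = field(default_factory=dict)  # shapely geometries, planar metres

    def to_geojson(self, colony: tuple) -> dict:
        feats = []
        for lv in self.levels:
            geom = self.polygons[lv]
            geo = _planar_geojson_to_geographic(mapping(geom), colony)
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"level": lv, "area_km2": self.areas_km2[lv]},
                    "geometry": geo,
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path, colony: tuple) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(colony), fh)


def _planar_geojson_to_geographic(geo: dict, colony: tuple) -> dict:
    def conv(coords):
        if coords and isinstance(coords[0], (int, float)):
            lat, lon = unproject_from_plane(coords[0], coords[1], colony)
            return [float(lon), float(lat)]
        return [conv(c) for c in coords]

    out = dict(geo)
    out["coordinates"] = conv(geo["coordinates"])
    return out


def reference_bandwidth(points: np.ndarray) -> float:
    """Normal-scale (reference) bandwidth: h = sigma * n^(-1/6) with
    sigma pooled over both axes."""
    n = len(points)
    sx = points[:, 0].std(ddof=1)
    sy = points[:, 1].std(ddof=1)
    return float(np.sqrt(0.5 * (sx**2 + sy**2)) * n ** (-1.0 / 6.0))


def kernel_ud(
    points: np.ndarray,
    bandwidth_m: float | None = None,
    cell_m: float = 250.0,
    levels=DEFAULT_LEVELS,
    build_polygons: bool = True,
) -> tuple[UdGrid, IsoplethSet]:
    """Bivariate Gaussian kernel UD and its isopleths.

    The grid covers the point bounding box padded by three bandwidths;
    density is a binned kernel estimate (histogram convolved with the
    Gaussian kernel) normalised to unit mass.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("kernel UD requires at least 5 planar points")
    if not all(0 < lv < 1 for lv in levels):
        raise ValueError("isopleth levels must lie in (0, 1)")
    h = reference_bandwidth(pts) if bandwidth_m is None else float(bandwidth_m)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pad = 3.0 * h
    x0, x1 = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    y0, y1 = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    x_edges = np.arange(x0, x1 + cell_m, cell_m)
    y_edges = np.arange(y0, y1 + cell_m, cell_m)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(x_edges, y_edges))
    density = ndimage.gaussian_filter(hist, sigma=h / cell_m, mode="constant")
    density /= density.sum()
    grid = UdGrid(x_edges=x_edges, y_edges=y_edges, density=density, cell_m=cell_m,
                  bandwidth_m=h)

    iso = IsoplethSet(levels=tuple(sorted(levels)))
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order])
    for lv in iso.levels:
        k = int(np.searchsorted(cum, lv)) + 1  # smallest top-density set with mass >= lv
        sel = order[:k]
        iso.masses[lv] = float(cum[k - 1])
        iso.areas_km2[lv] = k * grid.cell_area_km2
        if build_polygons:
            ii, jj = np.unravel_index(sel, density.shape)
            cells = [
                box(x_edges[i], y_edges[j], x_edges[i + 1], y_edges[j + 1])
                for i, j in zip(ii, jj)
            ]
            iso.polygons[lv] = unary_union(cells)
    return grid, iso
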