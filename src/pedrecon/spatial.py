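"""Synthetic home ranges, minimum convex polygons, grids and utilization.

The real study system used GPS-collar location clouds to give each
simulated animal a realistic home range.  Those collar data are not
distributable, so this module generates synthetic location clouds:
isotropic bivariate-normal point sets around a per-animal centroid,
with a sex-specific spread, a tighter winter cloud offset from the
annual centroid, and a 100% minimum convex polygon (MCP, the convex
hull of the cloud) derived from each cloud.  All spatial results built
on this layer are qualitative stand-ins for the collar-driven original.

Coordinates are planar kilometres; the study area defaults to a
50 x 33 km rectangle (1650 km^2) with its lower-left corner at the
origin.  Grid cells are 1 km^2, half-open ``[x, x+1) x [y, y+1)``,
indexed row-major from the lower-left corner.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import gaussian_kde
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.prepared import prep
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "StudyArea",
    "HomeRangeParams",
    "HomeRange",
    "CellWeightMap",
    "generate_home_range",
    "mcp_overlap",
    "disperse_yearling",
    "cell_weights",
    "utilization_map",
    "utilization",
]


@dataclass(frozen=True)
class StudyArea:
    """A study polygon with a square sampling grid over its bounding box."""

    polygon: Polygon
    cell_size: float = 1.0

    @classmethod
    def rectangle(cls, width: float = 50.0, height: float = 33.0,
                  cell_size: float = 1.0) -> "StudyArea":
        return cls(box(0.0, 0.0, width, height), cell_size=cell_size)

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise ValueError("study area must have positive area")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @cached_property
    def _origin(self) -> tuple[float, float]:
        minx, miny, _, _ = self.polygon.bounds
        return (minx, miny)

    @cached_property
    def grid_shape(self) -> tuple[int, int]:
        """(n_cols, n_rows) of the grid tiling the polygon's bounding box."""
        minx, miny, maxx, maxy = self.polygon.bounds
        nx = int(math.ceil((maxx - minx) / self.cell_size - 1e-9))
        ny = int(math.ceil((maxy - miny) / self.cell_size - 1e-9))
        return (nx, ny)

    @property
    def n_cells(self) -> int:
        nx, ny = self.grid_shape
        return nx * ny

    def cell_polygon(self, idx: int) -> Polygon:
        nx, ny = self.grid_shape
        if not 0 <= idx < nx * ny:
            raise IndexError(f"cell index {idx} outside grid of {nx * ny} cells")
        ox, oy = self._origin
        row, col = divmod(idx, nx)
        x0 = ox + col * self.cell_size
        y0 = oy + row * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def cell_index(self, x: float, y: float) -> int:
        ox, oy = self._origin
        nx, ny = self.grid_shape
        col = int((x - ox) // self.cell_size)
        row = int((y - oy) // self.cell_size)
        col = min(max(col, 0), nx - 1)
        row = min(max(row, 0), ny - 1)
        return row * nx + col

    @cached_property
    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, row-major order."""
        nx, ny = self.grid_shape
        ox, oy = self._origin
        cols = ox + (np.arange(nx) + 0.5) * self.cell_size
        rows = oy + (np.arange(ny) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(cols, rows)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @cached_property
    def _cell_tree(self) -> STRtree:
        return STRtree([self.cell_polygon(i) for i in range(self.n_cells)])

    def cells_intersecting(self, geom) -> np.ndarray:
        """Sorted indices of grid cells whose square intersects ``geom``."""
        idx = self._cell_tree.query(geom, predicate="intersects")
        return np.sort(np.asarray(idx, dtype=int))

    @cached_property
    def _prepared(self):
        return prep(self.polygon)

    def contains_geom(self, geom) -> bool:
        return self._prepared.intersects(geom)

    def sample_point(self, rng: np.random.Generator) -> tuple[float, float]:
        """Uniform random point inside the study polygon (rejection sampling)."""
        minx, miny, maxx, maxy = self.polygon.bounds
        while True:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if self._prepared.contains(Point(x, y)):
                return (x, y)


@dataclass(frozen=True)
class HomeRangeParams:
    """Spread and size of the synthetic location clouds.

    The spreads are free parameters of the synthetic layer (the collar
    data they replace are unavailable); defaults give median annual MCP
    areas of roughly 25 km^2 (females) and 55 km^2 (males) and winter
    ranges of a few km^2, in line with moose in northern New England.
    """

    n_annual: int = 50
    n_winter: int = 30
    sigma_annual_f: float = 1.0   # km
    sigma_annual_m: float = 1.5
    sigma_winter_f: float = 0.40
    sigma_winter_m: float = 0.55
    winter_offset_sd: float = 1.0  # km offset of winter centroid from annual

    def sigma(self, sex: str, season: str) -> float:
        if season == "annual":
            s = self.sigma_annual_f if sex == "F" else self.sigma_annual_m
        else:
            s = self.sigma_winter_f if sex == "F" else self.sigma_winter_m
        return s

    def __post_init__(self) -> None:
        for name in ("sigma_annual_f", "sigma_annual_m", "sigma_winter_f", "sigma_winter_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_annual < 3 or self.n_winter < 3:
            raise ValueError("need at least 3 points per location cloud")


@dataclass
class HomeRange:
    """A location cloud for one animal and season, with its 100% MCP."""

    owner: int
    season: str  # "winter" | "annual"
    centroid: tuple[float, float]
    points: np.ndarray  # (n, 2)

    @cached_property
    def mcp(self):
        """100% minimum convex polygon: the convex hull of the cloud.

        Degenerates to a point or segment for collinear clouds; shapely
        predicates still apply.
        """
        return MultiPoint(self.points).convex_hull


def generate_home_range(
    owner: int,
    sex: str,
    centroid: tuple[float, float],
    params: HomeRangeParams,
    rng: np.random.Generator,
) -> tuple[HomeRange, HomeRange]:
    """Synthetic (winter, annual) home-range pair around a centroid.

    The annual cloud is an isotropic bivariate normal around the
    centroid; the winter cloud is a tighter normal around a
    winter-specific centroid offset from the annual one.
    """
    cx, cy = centroid
    sa = params.sigma(sex, "annual")
    annual_pts = rng.normal(loc=(cx, cy), scale=sa, size=(params.n_annual, 2))
    wx, wy = rng.normal(loc=(cx, cy), scale=params.winter_offset_sd, size=2)
    sw = params.sigma(sex, "winter")
    winter_pts = rng.normal(loc=(wx, wy), scale=sw, size=(params.n_winter, 2))
    annual = HomeRange(owner, "annual", (cx, cy), annual_pts)
    winter = HomeRange(owner, "winter", (wx, wy), winter_pts)
    return winter, annual


def mcp_overlap(a: HomeRange, b: HomeRange) -> bool:
    """True iff the two 100% MCPs intersect (shared boundary counts)."""
    if len(a.points) == 0 or len(b.points) == 0:
        raise ValueError("location clouds must be non-empty")
    return bool(a.mcp.intersects(b.mcp))


def disperse_yearling(
    sex: str,
    origin: tuple[float, float],
    dispersal_mean_km: float,
    dispersal_sd_km: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """New centroid after yearling natal dispersal.

    Bearing is uniform on [0, 360); distance is normal with the
    sex-specific mean and spread, truncated at zero (negative draws are
    rejected and redrawn).
    """
    bearing = rng.uniform(0.0, 2.0 * math.pi)
    if dispersal_sd_km == 0.0:
        distance = dispersal_mean_km
    else:
        distance = rng.normal(dispersal_mean_km, dispersal_sd_km)
        while distance < 0.0:
            distance = rng.normal(dispersal_mean_km, dispersal_sd_km)
    return (origin[0] + distance * math.cos(bearing),
            origin[1] + distance * math.sin(bearing))


@dataclass
class CellWeightMap:
    """Per-cell counts of intersecting annual MCPs, scaled to [0, 1]."""

    counts: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "CellWeightMap":
        counts = np.asarray(counts, dtype=float)
        peak = counts.max() if counts.size else 0.0
        weights = counts / peak if peak > 0 else np.zeros_like(counts)
        return cls(counts=counts, weights=weights)


def cell_weights(home_ranges: Iterable[HomeRange], area: StudyArea) -> CellWeightMap:
    """Number of animals whose annual MCP intersects each grid cell.

    Counts are scaled by the busiest cell so the heaviest-use cell has
    weight 1 (all zeros if the population is empty).
    """
    counts = np.zeros(area.n_cells, dtype=float)
    for hr in home_ranges:
        idx = area.cells_intersecting(hr.mcp)
        counts[idx] += 1.0
    return CellWeightMap.from_counts(counts)


def utilization_map(winter: HomeRange, area: StudyArea) -> dict[int, float]:
    """Scaled winter utilization of each grid cell the animal's MCP touches.

    A Gaussian kernel density (normal-reference bandwidth) is fitted to
    the winter cloud and evaluated at the centers of the cells the
    winter MCP intersects; values are scaled so the animal's busiest
    cell equals 1 (ties broken toward the lowest cell index).  Cells
    outside the MCP neighbourhood are implicitly zero.  A degenerate
    (single-point) cloud yields 1 on the containing cell only.
    """
    if len(winter.points) == 0:
        raise ValueError("winter location cloud must be non-empty")
    cells = area.cells_intersecting(winter.mcp)
    if cells.size == 0:
        return {}
    spread = float(np.ptp(winter.points, axis=0).max())
    if spread < 1e-9 or len(winter.points) < 3:
        cx, cy = winter.points.mean(axis=0)
        return {area.cell_index(cx, cy): 1.0}
    try:
        kde = gaussian_kde(winter.points.T)
        values = kde(area.cell_centers[cells].T)
    except np.linalg.LinAlgError:
        cx, cy = winter.points.mean(axis=0)
        return {area.cell_index(cx, cy): 1.0}
    peak = values.max()
    if peak <= 0:
        cx, cy = winter.points.mean(axis=0)
        return {area.cell_index(cx, cy): 1.0}
    scaled = values / peak
    top = int(np.flatnonzero(scaled == scaled.max())[0])
    if np.sum(scaled == 1.0) > 1:
        logger.debug("utilization tie for animal %s broken toward cell %d",
                     winter.owner, cells[top])
        scaled = np.where(scaled == 1.0, np.nextafter(1.0, 0.0), scaled)
        scaled[top] = 1.0
    return {int(c): float(v) for c, v in zip(cells, scaled)}


def utilization(winter: HomeRange, cell: int, area: StudyArea) -> float:
    """Scaled utilization of one cell (0 outside the evaluated neighbourhood)."""
    return utilization_map(winter, area).get(cell, 0.0)
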