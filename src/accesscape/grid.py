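"""Georeferenced raster data model and combined land-cover construction.

Conventions used throughout the package:

* Coordinates are projected meters (a UTM-like CRS; only the label is carried).
* Grid indexing is ``(row, col)`` with row 0 at the **north** edge.
* ``origin_x`` is the west edge, ``origin_y`` the north edge; the center of
  cell ``(r, c)`` is ``(origin_x + (c + 0.5) * cell, origin_y - (r + 0.5) * cell)``.
* Polyline rasterization uses a center-within-half-cell rule: a cell is burned
  when its center lies within ``cell_size / 2`` of the line.  Polygons burn
  cells whose center is covered by the polygon.  The rule is fixed for
  reproducibility.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon, box
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

NODATA_CODE = -1


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a uniform raster lattice (projected meters)."""

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0  # north (top) edge
    crs_label: str = "local-projected-meters"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width_m(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height_m(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.height_m,
            self.origin_x + self.width_m,
            self.origin_y,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of all cell-center coordinates, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.origin_x + (cols + 0.5) * self.cell_size
        ys = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)[0], np.meshgrid(xs, ys)[1]

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Cell index containing a point (points on an edge go to the SE cell)."""
        col = int(math.floor((x - self.origin_x) / self.cell_size))
        row = int(math.floor((self.origin_y - y) / self.cell_size))
        return row, col

    def world_to_cell_arrays(
        self, xs: np.ndarray, ys: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        cols = np.floor((np.asarray(xs) - self.origin_x) / self.cell_size).astype(int)
        rows = np.floor((self.origin_y - np.asarray(ys)) / self.cell_size).astype(int)
        return rows, cols

    def contains_point(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax

    def contains_cell(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


class LandClass(enum.IntEnum):
    """Combined land-cover classes.

    The six non-road cover classes, six road classes and the boat corridor
    make up the thirteen analysis classes; ``RIVER_BARRIER`` is an internal
    fourteenth code that keeps burned-in river cells distinguishable from
    wetland while behaving identically (impassable in every scenario).
    Open water (the lake) is coded ``WETLAND``: it is impassable to every
    land mode, and the boat corridor is burned over it.
    """

    FORESTLAND = 1
    GRASSLAND = 2
    CROPLAND = 3
    SETTLEMENT = 4
    WETLAND = 5
    OTHER_LAND = 6
    RIVER_BARRIER = 7
    BOAT_ROUTE = 8
    MAJOR_ROAD = 9
    MAJOR_ROAD_RESIDENTIAL = 10
    SECONDARY_ROAD = 11
    LOCAL_ROAD_ALL = 12
    LOCAL_ROAD_MOTO_BIKE = 13
    LOCAL_ROAD_WALK = 14


BARRIER_CLASSES = frozenset({LandClass.WETLAND, LandClass.RIVER_BARRIER})
ROAD_CLASSES = frozenset(
    {
        LandClass.MAJOR_ROAD,
        LandClass.MAJOR_ROAD_RESIDENTIAL,
        LandClass.SECONDARY_ROAD,
        LandClass.LOCAL_ROAD_ALL,
        LandClass.LOCAL_ROAD_MOTO_BIKE,
        LandClass.LOCAL_ROAD_WALK,
    }
)
COVER_CLASSES = frozenset(
    {
        LandClass.FORESTLAND,
        LandClass.GRASSLAND,
        LandClass.CROPLAND,
        LandClass.SETTLEMENT,
        LandClass.WETLAND,
        LandClass.OTHER_LAND,
    }
)

MAX_CLASS_CODE = max(int(c) for c in LandClass)


def class_from_name(name: str) -> LandClass:
    try:
        return LandClass[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown land class {name!r}; valid: "
            + ", ".join(c.name.lower() for c in LandClass)
        ) from None


@dataclass
class ClassRaster:
    """Integer class-coded raster on a :class:`GridSpec` lattice."""

    grid: GridSpec
    values: np.ndarray
    nodata_code: int = NODATA_CODE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        self.validate_codes()

    def validate_codes(self) -> None:
        codes = np.unique(self.values)
        valid = {int(c) for c in LandClass} | {self.nodata_code}
        bad = [int(c) for c in codes if int(c) not in valid]
        if bad:
            raise ValueError(f"unregistered land-class codes present: {bad}")

    def copy(self) -> "ClassRaster":
        return ClassRaster(self.grid, self.values.copy(), self.nodata_code)


@dataclass
class Dem:
    """Elevation raster (meters above sea level)."""

    grid: GridSpec
    elevation: np.ndarray

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != self.grid.shape:
            raise ValueError("DEM shape does not match its grid")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("DEM contains non-finite elevations")


CARE_LEVELS = ("CEmONC", "CEmONC_minus_1", "BEmONC_minus_1", "non_EmONC")
EMONC_LEVELS = frozenset({"CEmONC", "CEmONC_minus_1", "BEmONC_minus_1"})


@dataclass(frozen=True)
class Facility:
    """A health facility point with its care-level attribute.

    ``is_emonc`` is derived: comprehensive (CEmONC), partially functional
    comprehensive (CEmONC-1) and partially functional basic (BEmONC-1)
    facilities all count as EmONC service points.
    """

    id: str
    x: float
    y: float
    care_level: str = "non_EmONC"

    def __post_init__(self) -> None:
        if self.care_level not in CARE_LEVELS:
            raise ValueError(
                f"care_level {self.care_level!r} not in {CARE_LEVELS}"
            )

    @property
    def is_emonc(self) -> bool:
        return self.care_level in EMONC_LEVELS


@dataclass(frozen=True)
class Feature:
    """One vector feature: a shapely geometry plus a class / attribute tag."""

    geometry: BaseGeometry
    tag: LandClass | str | None = None


@dataclass
class VectorLayer:
    """Homogeneous collection of vector features in the analysis CRS."""

    geometry_kind: str  # "polyline" | "polygon" | "point"
    features: list[Feature] = field(default_factory=list)
    crs_label: str = "local-projected-meters"

    _KINDS = {"polyline": ("LineString", "MultiLineString"),
              "polygon": ("Polygon", "MultiPolygon"),
              "point": ("Point", "MultiPoint")}

    def __post_init__(self) -> None:
        if self.geometry_kind not in self._KINDS:
            raise ValueError(f"geometry_kind must be one of {sorted(self._KINDS)}")
        allowed = self._KINDS[self.geometry_kind]
        for f in self.features:
            if f.geometry.geom_type not in allowed:
                raise ValueError(
                    f"{f.geometry.geom_type} feature in a {self.geometry_kind} layer"
                )
            if not f.geometry.is_valid:
                raise ValueError("invalid geometry in layer")


# ---------------------------------------------------------------------------
# rasterization


def _burn_geometry(
    geom: BaseGeometry,
    grid: GridSpec,
    out: np.ndarray,
    code: int,
    kind: str,
) -> None:
    """Burn one geometry into ``out`` using the center rule."""
    half = grid.cell_size / 2.0
    pad = half * 1.001  # guard band for centers exactly at the threshold
    gxmin, gymin, gxmax, gymax = geom.bounds
    xmin, ymin, xmax, ymax = grid.bounds
    if gxmax < xmin - pad or gxmin > xmax + pad or gymax < ymin - pad or gymin > ymax + pad:
        log.warning("feature entirely outside grid bounds; skipped")
        return
    if gxmin < xmin or gymin < ymin or gxmax > xmax or gymax > ymax:
        log.warning("feature extends outside grid bounds; clipped to grid")

    # candidate index window
    c0 = max(0, int(math.floor((gxmin - pad - xmin) / grid.cell_size)))
    c1 = min(grid.n_cols - 1, int(math.ceil((gxmax + pad - xmin) / grid.cell_size)))
    r0 = max(0, int(math.floor((ymax - (gymax + pad)) / grid.cell_size)))
    r1 = min(grid.n_rows - 1, int(math.ceil((ymax - (gymin - pad)) / grid.cell_size)))
    if c1 < c0 or r1 < r0:
        return
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cx = xmin + (cols + 0.5) * grid.cell_size
    cy = ymax - (rows + 0.5) * grid.cell_size
    XX, YY = np.meshgrid(cx, cy)
    pts = shapely.points(XX.ravel(), YY.ravel())
    if kind == "polyline":
        hit = shapely.dwithin(pts, geom, half)
    else:  # polygon
        hit = shapely.covers(geom, pts)
    hit = hit.reshape(XX.shape)
    sub = out[r0 : r1 + 1, c0 : c1 + 1]
    sub[hit] = code


def rasterize_layer(
    layer: VectorLayer,
    grid: GridSpec,
    burn_code: LandClass | int | None = None,
) -> ClassRaster:
    """Rasterize a vector layer onto the grid.

    Cells whose center lies within ``cell_size/2`` of a polyline (or inside a
    polygon) get the burn code; all other cells are nodata.  When
    ``burn_code`` is None each feature burns its own class tag.  Features
    outside the grid are silently clipped (with a logged warning); an empty
    layer yields an all-nodata mask.
    """
    out = np.full(grid.shape, NODATA_CODE, dtype=np.int16)
    for f in layer.features:
        code = burn_code if burn_code is not None else f.tag
        if code is None:
            raise ValueError("feature has no class tag and no burn_code was given")
        if isinstance(code, str):
            code = class_from_name(code)
        if layer.geometry_kind == "point":
            geoms = getattr(f.geometry, "geoms", [f.geometry])
            for g in geoms:
                if not grid.contains_point(g.x, g.y):
                    log.warning("point feature outside grid bounds; skipped")
                    continue
                r, c = grid.world_to_cell(g.x, g.y)
                r = min(r, grid.n_rows - 1)
                c = min(c, grid.n_cols - 1)
                out[r, c] = int(code)
        else:
            _burn_geometry(f.geometry, grid, out, int(code), layer.geometry_kind)
    return ClassRaster(grid, out)


def build_combined_landcover(
    base: ClassRaster,
    rivers: VectorLayer | None = None,
    roads: VectorLayer | None = None,
    boat_routes: VectorLayer | None = None,
) -> ClassRaster:
    """Overlay rivers, roads and boat corridors on a base land-cover raster.

    Burn order is base < rivers (RIVER_BARRIER) < roads (their road class)
    < boat routes (BOAT_ROUTE): later burns overwrite earlier ones, so a road
    cell crossing a river stays passable (implicit bridge).  Major-road cells
    whose base cover is settlement are recoded MAJOR_ROAD_RESIDENTIAL
    ("major roads crossing residential areas").
    """
    combined = base.values.copy()
    grid = base.grid
    if np.any(combined == base.nodata_code):
        raise ValueError("base land cover has nodata cells inside the region")

    def _check(layer: VectorLayer | None) -> None:
        if layer is not None and layer.crs_label != grid.crs_label:
            raise ValueError(
                f"layer CRS {layer.crs_label!r} != grid CRS {grid.crs_label!r}"
            )

    for layer in (rivers, roads, boat_routes):
        _check(layer)

    if rivers is not None and rivers.features:
        mask = rasterize_layer(rivers, grid, LandClass.RIVER_BARRIER)
        combined[mask.values != NODATA_CODE] = int(LandClass.RIVER_BARRIER)
    if roads is not None and roads.features:
        mask = rasterize_layer(roads, grid, burn_code=None)
        burned = mask.values != NODATA_CODE
        combined[burned] = mask.values[burned]
        residential = (
            (mask.values == int(LandClass.MAJOR_ROAD))
            & (base.values == int(LandClass.SETTLEMENT))
        )
        combined[residential] = int(LandClass.MAJOR_ROAD_RESIDENTIAL)
    if boat_routes is not None and boat_routes.features:
        mask = rasterize_layer(boat_routes, grid, LandClass.BOAT_ROUTE)
        combined[mask.values != NODATA_CODE] = int(LandClass.BOAT_ROUTE)
    return ClassRaster(grid, combined, base.nodata_code)


# ---------------------------------------------------------------------------
# facility placement


@dataclass
class SnapResult:
    """Facility-to-grid snap outcome: unique source cells plus bookkeeping."""

    sources: list[tuple[int, int]]
    ids_by_cell: dict[tuple[int, int], list[str]]
    snapped: dict[str, tuple[tuple[int, int], tuple[int, int]]]  # id -> (raw, snapped)


def snap_facilities(
    facilities: Sequence[Facility],
    combined: ClassRaster,
    snap_radius_cells: int = 10,
    barrier_codes: Iterable[int] = tuple(int(c) for c in BARRIER_CLASSES),
) -> SnapResult:
    """Map facility points to passable source cells.

    Each facility goes to the cell containing its coordinates; a facility on
    a barrier cell is moved to the nearest passable cell within
    ``snap_radius_cells`` (ties broken by distance, then row, then col).
    Multiple facilities in one cell collapse to a single source cell.
    """
    grid = combined.grid
    barrier = np.isin(combined.values, np.fromiter(barrier_codes, dtype=np.int16))
    sources: list[tuple[int, int]] = []
    ids_by_cell: dict[tuple[int, int], list[str]] = {}
    snapped: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
    for fac in facilities:
        if not grid.contains_point(fac.x, fac.y):
            raise ValueError(f"facility {fac.id!r} lies outside the grid")
        r, c = grid.world_to_cell(fac.x, fac.y)
        r = min(r, grid.n_rows - 1)
        c = min(c, grid.n_cols - 1)
        cell = (r, c)
        if barrier[r, c]:
            cell = _nearest_passable(barrier, r, c, snap_radius_cells)
            if cell is None:
                raise ValueError(
                    f"facility {fac.id!r} has no passable cell within "
                    f"{snap_radius_cells} cells of ({r}, {c})"
                )
            log.info("facility %s snapped from %s to %s", fac.id, (r, c), cell)
            snapped[fac.id] = ((r, c), cell)
        if cell not in ids_by_cell:
            ids_by_cell[cell] = []
            sources.append(cell)
        ids_by_cell[cell].append(fac.id)
    return SnapResult(sources=sources, ids_by_cell=ids_by_cell, snapped=snapped)


def _nearest_passable(
    barrier: np.ndarray, r: int, c: int, radius: int
) -> tuple[int, int] | None:
    n_rows, n_cols = barrier.shape
    best: tuple[float, int, int] | None = None
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                continue
            if barrier[rr, cc]:
                continue
            d = math.hypot(dr, dc)
            if d > radius:
                continue
            key = (d, rr, cc)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return (best[1], best[2])


# ---------------------------------------------------------------------------
# slope


def directional_slope(
    dem: Dem,
    from_cell: tuple[int, int],
    to_cell: tuple[int, int],
    connectivity: int = 8,
) -> float:
    """Rise-over-run between adjacent cell centers, signed in travel direction.

    Antisymmetric: ``slope(a, b) == -slope(b, a)``.
    """
    dr = to_cell[0] - from_cell[0]
    dc = to_cell[1] - from_cell[1]
    offsets = neighbor_offsets(connectivity)
    if (dr, dc) not in offsets:
        raise ValueError(
            f"cells {from_cell} and {to_cell} are not adjacent under "
            f"{connectivity}-connectivity"
        )
    for cell in (from_cell, to_cell):
        if not dem.grid.contains_cell(*cell):
            raise ValueError(f"cell {cell} outside grid")
    run = math.hypot(dr, dc) * dem.grid.cell_size
    rise = dem.elevation[to_cell] - dem.elevation[from_cell]
    return rise / run


def neighbor_offsets(connectivity: int) -> list[tuple[int, int]]:
    """Neighbor step offsets: 8 (queen) or 16 (queen + knight moves)."""
    if connectivity not in (8, 16):
        raise ValueError("connectivity must be 8 or 16")
    queen = [
        (dr, dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]
    if connectivity == 8:
        return queen
    knight = [
        (dr, dc)
        for dr in (-2, -1, 1, 2)
        for dc in (-2, -1, 1, 2)
        if abs(dr) != abs(dc)
    ]
    return queen + knight
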