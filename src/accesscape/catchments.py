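"""Travel-time zones, 2-hour catchments and the mode-combination map.

Good geographic access is defined as a travel time at or under 2 hours;
surfaces are banded into four incremental 30-minute zones (0–30, 31–60,
61–90, 91–120) plus an over-2-hours band that also absorbs unreachable
cells.  Zone upper bounds are closed, so exactly 120 minutes is still good
access.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from shapely import unary_union
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from accesscape.cost import TravelTimeSurface
from accesscape.grid import Feature, GridSpec, VectorLayer


class Zone(enum.IntEnum):
    Z0_30 = 0
    Z31_60 = 1
    Z61_90 = 2
    Z91_120 = 3
    OVER_120 = 4


ZONE_LABELS = {
    Zone.Z0_30: "0-30",
    Zone.Z31_60: "31-60",
    Zone.Z61_90: "61-90",
    Zone.Z91_120: "91-120",
    Zone.OVER_120: ">120",
}

DEFAULT_BREAKS = (30.0, 60.0, 90.0, 120.0)
GOOD_ACCESS_MINUTES = 120.0


@dataclass
class ZoneRaster:
    """Categorical raster of travel-time bands (partition of all cells)."""

    grid: GridSpec
    zone: np.ndarray
    breaks: tuple[float, ...] = DEFAULT_BREAKS

    def __post_init__(self) -> None:
        self.zone = np.asarray(self.zone, dtype=np.int8)
        if self.zone.shape != self.grid.shape:
            raise ValueError("zone shape does not match grid")

    def counts(self) -> dict[Zone, int]:
        binc = np.bincount(self.zone.ravel(), minlength=len(Zone))
        return {z: int(binc[z]) for z in Zone}


@dataclass
class CatchmentMask:
    """Boolean raster of cells within the good-access threshold."""

    grid: GridSpec
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")


@dataclass
class ModeCombinationMap:
    """Per-cell set of scenarios whose 2-hour catchment contains the cell.

    Stored as a bitmask over ``scenario_ids`` (bit i set when scenario i
    reaches the cell within the threshold).
    """

    grid: GridSpec
    bits: np.ndarray
    scenario_ids: tuple[str, ...]

    def combo_at(self, row: int, col: int) -> frozenset[str]:
        b = int(self.bits[row, col])
        return frozenset(
            sid for i, sid in enumerate(self.scenario_ids) if b & (1 << i)
        )

    def combo_counts(self) -> dict[frozenset[str], int]:
        out: dict[frozenset[str], int] = {}
        binc = np.bincount(self.bits.ravel(), minlength=1 << len(self.scenario_ids))
        for b, n in enumerate(binc):
            if n:
                combo = frozenset(
                    sid for i, sid in enumerate(self.scenario_ids) if b & (1 << i)
                )
                out[combo] = int(n)
        return out


def classify_zones(
    surface: TravelTimeSurface,
    breaks: tuple[float, ...] | list[float] = DEFAULT_BREAKS,
) -> ZoneRaster:
    """Band a travel-time surface into 30-minute zones (closed upper bounds).

    Minutes ``m`` map to the first zone with ``m <= break``; anything above
    the last break — including unreachable cells — is the over-threshold band.
    """
    breaks = tuple(float(b) for b in breaks)
    if not breaks or any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be non-empty and strictly increasing")
    if len(breaks) != len(Zone) - 1:
        raise ValueError(f"expected {len(Zone) - 1} breaks, got {len(breaks)}")
    m = surface.minutes
    zone = np.full(surface.grid.shape, int(Zone.OVER_120), dtype=np.int8)
    # assign from the widest band inward so the first (tightest) band wins
    for z, b in zip(reversed(list(Zone)[:-1]), reversed(breaks)):
        zone[m <= b] = int(z)
    zone[surface.unreachable] = int(Zone.OVER_120)
    return ZoneRaster(surface.grid, zone, breaks)


def two_hour_catchment(
    surface: TravelTimeSurface,
    threshold_minutes: float = GOOD_ACCESS_MINUTES,
) -> CatchmentMask:
    """Cells with travel time at or under the threshold (default 2 hours)."""
    inside = (surface.minutes <= threshold_minutes) & ~surface.unreachable
    return CatchmentMask(surface.grid, inside)


def all_modes_minimum(surfaces: dict[str, TravelTimeSurface]) -> TravelTimeSurface:
    """Best case over scenarios: cell-wise minimum travel time.

    A cell is unreachable only where every input leaves it unreachable.
    """
    if not surfaces:
        raise ValueError("at least one surface required")
    items = list(surfaces.values())
    grid = items[0].grid
    for s in items[1:]:
        if s.grid != grid:
            raise ValueError("surfaces are not co-registered")
    minutes = np.minimum.reduce([s.minutes for s in items])
    return TravelTimeSurface(grid, minutes, scenario_id="all_modes")


def mode_combination_map(
    surfaces: dict[str, TravelTimeSurface],
    threshold_minutes: float = GOOD_ACCESS_MINUTES,
) -> ModeCombinationMap:
    """Which scenarios reach each cell within the threshold (map of combos)."""
    if not surfaces:
        raise ValueError("at least one surface required")
    sids = tuple(surfaces.keys())
    grid = surfaces[sids[0]].grid
    bits = np.zeros(grid.shape, dtype=np.uint8)
    for i, sid in enumerate(sids):
        s = surfaces[sid]
        if s.grid != grid:
            raise ValueError("surfaces are not co-registered")
        inside = (s.minutes <= threshold_minutes) & ~s.unreachable
        bits |= inside.astype(np.uint8) << i
    return ModeCombinationMap(grid, bits, sids)


def vectorize_zones(zones: ZoneRaster) -> VectorLayer:
    """Dissolve each zone band into a (multi)polygon layer.

    The union of per-cell squares per category; re-rasterizing the result on
    the same grid (center-within rule) reproduces the zone raster exactly.
    """
    grid = zones.grid
    xmin, _, _, ymax = grid.bounds
    cs = grid.cell_size
    features: list[Feature] = []
    for z in Zone:
        rows, cols = np.nonzero(zones.zone == int(z))
        if rows.size == 0:
            continue
        boxes = [
            box(
                xmin + c * cs,
                ymax - (r + 1) * cs,
                xmin + (c + 1) * cs,
                ymax - r * cs,
            )
            for r, c in zip(rows.tolist(), cols.tolist())
        ]
        geom: BaseGeometry = unary_union(boxes)
        features.append(Feature(geom, z.name.lower()))
    return VectorLayer("polygon", features, crs_label=grid.crs_label)


def rasterize_zone_polygons(layer: VectorLayer, grid: GridSpec) -> ZoneRaster:
    """Inverse of :func:`vectorize_zones` on the same grid."""
    from accesscape.grid import rasterize_layer  # local import avoids cycle

    zone = np.full(grid.shape, int(Zone.OVER_120), dtype=np.int8)
    for f in layer.features:
        z = Zone[str(f.tag).upper()]
        mask = rasterize_layer(
            VectorLayer("polygon", [Feature(f.geometry, None)],
                        crs_label=layer.crs_label),
            grid,
            burn_code=1,
        )
        zone[mask.values == 1] = int(z)
    return ZoneRaster(grid, zone)
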