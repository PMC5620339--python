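"""Zonal birth statistics, access proportions and facility-upgrade ranking.

The live-birth raster (nominally 100 m cells) is a proxy for women needing
delivery care.  It is never resampled: each birth cell is assigned to the
travel-time zone (or council) containing its center, so counts are conserved
exactly.  Proportions of births per zone, and per-council proportions of
births with poor access (> 2 h), mirror the study's regional and district
reporting; the expected number of births in a catchment is the product of
the female population of reproductive age, an annual growth coefficient, a
fertility rate and the catchment's birth proportion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from accesscape.catchments import (
    GOOD_ACCESS_MINUTES,
    Zone,
    ZoneRaster,
)
from accesscape.cost import (
    EngineConfig,
    TravelTimeSurface,
    accumulate_travel_time,
)
from accesscape.grid import ClassRaster, Dem, Facility, GridSpec, snap_facilities
from accesscape.scenarios import SpeedTable, ToblerParams

log = logging.getLogger(__name__)


@dataclass
class BirthRaster:
    """Gridded expected live-birth counts (its own lattice, often coarser)."""

    grid: GridSpec
    births: np.ndarray

    def __post_init__(self) -> None:
        self.births = np.asarray(self.births, dtype=float)
        if self.births.shape != self.grid.shape:
            raise ValueError("births shape does not match grid")
        if np.any(self.births < 0) or not np.all(np.isfinite(self.births)):
            raise ValueError("birth counts must be finite and non-negative")

    @property
    def total(self) -> float:
        return float(self.births.sum())


@dataclass
class AdminUnits:
    """Administrative-council polygons (non-overlapping) with names."""

    names: list[str]
    polygons: list[BaseGeometry]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.polygons):
            raise ValueError("names and polygons differ in length")


@dataclass
class DemographicParams:
    """Factors of the total-births product formula."""

    women_pop: float
    growth_coeff: float = 1.0
    fertility_rate: float = 0.2  # births per woman of reproductive age per year

    def __post_init__(self) -> None:
        if min(self.women_pop, self.growth_coeff, self.fertility_rate) <= 0:
            raise ValueError("demographic parameters must be positive")


@dataclass
class CoverageReport:
    """Birth counts/proportions per zone plus per-council poor-access shares."""

    scenario_id: str
    per_zone: dict[Zone, tuple[float, float]] = field(default_factory=dict)
    per_unit_poor: dict[str, float | None] = field(default_factory=dict)

    @property
    def poor_access_proportion(self) -> float:
        return self.per_zone[Zone.OVER_120][1]


# ---------------------------------------------------------------------------
# zonal statistics


def _birth_cell_lookup(
    births: BirthRaster, target: GridSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rows, cols, inside) of each birth-cell center on the target grid."""
    xs, ys = births.grid.cell_centers()
    rows, cols = target.world_to_cell_arrays(xs.ravel(), ys.ravel())
    inside = (
        (rows >= 0) & (rows < target.n_rows) & (cols >= 0) & (cols < target.n_cols)
    )
    return rows, cols, inside


def zonal_birth_counts(
    zones: ZoneRaster, births: BirthRaster
) -> dict[Zone, float]:
    """Births per travel-time zone by cell-center assignment (conserving).

    Each birth cell goes to the zone of the zone-raster cell containing its
    center; centers outside the zone grid fall in the over-threshold band
    (logged).  The counts always sum to the birth-raster total.
    """
    rows, cols, inside = _birth_cell_lookup(births, zones.grid)
    b = births.births.ravel()
    zone_of_birth = np.full(b.size, int(Zone.OVER_120), dtype=np.int8)
    zone_of_birth[inside] = zones.zone[rows[inside], cols[inside]]
    n_out = int((~inside & (b > 0)).sum())
    if n_out:
        log.warning(
            "%d birth cells with births fall outside the zone grid; "
            "assigned to the poor-access band", n_out,
        )
    sums = np.bincount(zone_of_birth, weights=b, minlength=len(Zone))
    return {z: float(sums[int(z)]) for z in Zone}


def proportion_per_zone(counts: dict[Zone, float]) -> dict[Zone, float]:
    """Normalize zonal counts to proportions of the regional total."""
    total = math.fsum(counts.values())
    if total <= 0:
        raise ValueError("total births must be positive")
    return {z: counts[z] / total for z in counts}


def poor_access_by_unit(
    surface: TravelTimeSurface,
    births: BirthRaster,
    units: AdminUnits,
    threshold_minutes: float = GOOD_ACCESS_MINUTES,
) -> dict[str, float | None]:
    """Per-council proportion of births with travel time over the threshold.

    Birth cells are assigned to councils by center containment; a council
    with zero births reports None (undefined), never zero.
    """
    rows, cols, inside = _birth_cell_lookup(births, surface.grid)
    b = births.births.ravel()
    poor = np.ones(b.size, dtype=bool)
    m = surface.minutes[rows[inside], cols[inside]]
    poor[inside] = ~(m <= threshold_minutes)

    xs, ys = births.grid.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    out: dict[str, float | None] = {}
    for name, poly in zip(units.names, units.polygons):
        member = shapely.covers(poly, pts)
        tot = float(b[member].sum())
        if tot <= 0:
            out[name] = None
        else:
            out[name] = float(b[member & poor].sum()) / tot
    return out


def build_report(
    surface: TravelTimeSurface,
    zones: ZoneRaster,
    births: BirthRaster,
    units: AdminUnits | None = None,
    threshold_minutes: float = GOOD_ACCESS_MINUTES,
) -> CoverageReport:
    counts = zonal_birth_counts(zones, births)
    props = proportion_per_zone(counts)
    per_zone = {z: (counts[z], props[z]) for z in Zone}
    per_unit = (
        poor_access_by_unit(surface, births, units, threshold_minutes)
        if units is not None
        else {}
    )
    return CoverageReport(surface.scenario_id, per_zone, per_unit)


def estimate_total_births(proportion: float, demo: DemographicParams) -> float:
    """Expected births in a catchment: pop × growth × fertility × proportion."""
    if not (0 <= proportion <= 1):
        raise ValueError("proportion must lie in [0, 1]")
    return demo.women_pop * demo.growth_coeff * demo.fertility_rate * proportion


# ---------------------------------------------------------------------------
# upgrade ranking


def _births_inside(
    minutes: np.ndarray,
    grid: GridSpec,
    births: BirthRaster,
    threshold: float,
) -> float:
    rows, cols, inside = _birth_cell_lookup(births, grid)
    b = births.births.ravel()
    good = np.zeros(b.size, dtype=bool)
    good[inside] = minutes[rows[inside], cols[inside]] <= threshold
    return float(b[good].sum())


def rank_upgrade_candidates(
    candidates: list[Facility],
    existing: list[Facility],
    combined: ClassRaster,
    dem: Dem,
    table: SpeedTable,
    births: BirthRaster,
    k: int = 1,
    greedy: bool = False,
    config: EngineConfig = EngineConfig(),
    params: ToblerParams = ToblerParams(),
    threshold_minutes: float = GOOD_ACCESS_MINUTES,
) -> list[tuple[Facility, float]]:
    """Rank candidate facilities by the births their upgrade would newly cover.

    A candidate's gain is the number of births inside the 2-hour catchment of
    the existing facilities plus the candidate, minus the births covered by
    the existing set alone — i.e. priority goes to facilities serving areas
    of currently poor access with a high birth density.  Ties break by
    facility id.  In greedy mode the best candidate is committed and gains
    are recomputed ``k`` times (coverage is a union, so greedy gains are
    non-increasing).
    """
    if not candidates:
        return []
    ids = {f.id for f in candidates} & {f.id for f in existing}
    if ids:
        raise ValueError(f"candidates overlap existing facilities: {sorted(ids)}")
    if k < 1:
        raise ValueError("k must be at least 1")

    base_src = snap_facilities(existing, combined).sources
    base = accumulate_travel_time(combined, dem, table, base_src, config, params)
    base_minutes = base.minutes

    cand_minutes: dict[str, np.ndarray] = {}
    for fac in candidates:
        src = snap_facilities([fac], combined).sources
        s = accumulate_travel_time(combined, dem, table, src, config, params)
        cand_minutes[fac.id] = s.minutes

    def gains(current: np.ndarray, pool: list[Facility]):
        covered = _births_inside(current, combined.grid, births, threshold_minutes)
        out = []
        for fac in pool:
            merged = np.minimum(current, cand_minutes[fac.id])
            g = _births_inside(merged, combined.grid, births, threshold_minutes)
            out.append((fac, g - covered))
        out.sort(key=lambda t: (-t[1], t[0].id))
        return out

    if not greedy:
        return gains(base_minutes, list(candidates))

    picks: list[tuple[Facility, float]] = []
    pool = list(candidates)
    current = base_minutes
    for _ in range(min(k, len(pool))):
        ranked = gains(current, pool)
        best, g = ranked[0]
        picks.append((best, g))
        pool = [f for f in pool if f.id != best.id]
        current = np.minimum(current, cand_minutes[best.id])
    return picks
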