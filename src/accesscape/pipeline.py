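"""End-to-end pipeline: surfaces → zones → catchments → birth coverage.

``run_analysis`` is the in-memory engine (used by the numbered analysis
drivers, the tests and the acceptance script); ``run_pipeline`` wraps it
with file I/O from a :class:`RunConfig`, writing, per scenario, the
travel-time surface, the zone raster, the 2-hour catchment and the coverage
table, then the all-modes surface, the mode-combination map and one JSON
summary (zone proportions per scenario plus per-council poor-access shares).
Outputs are deterministic: rerunning on the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from accesscape import __version__
from accesscape.catchments import (
    DEFAULT_BREAKS,
    Zone,
    ZONE_LABELS,
    all_modes_minimum,
    classify_zones,
    mode_combination_map,
    two_hour_catchment,
)
from accesscape.cost import EngineConfig, accumulate_travel_time
from accesscape.coverage import (
    AdminUnits,
    BirthRaster,
    CoverageReport,
    build_report,
)
from accesscape.grid import (
    ClassRaster,
    Dem,
    Facility,
    build_combined_landcover,
    snap_facilities,
)
from accesscape.io import (
    read_admin_units,
    read_facilities_csv,
    read_raster,
    read_vector_layer,
    write_ascii_grid,
    write_raster,
)
from accesscape.scenarios import (
    SCENARIO_IDS,
    ToblerParams,
    default_speed_table,
)


@dataclass
class RunConfig:
    """Paths and options of one pipeline run."""

    landcover: str = "landcover.asc"
    dem: str = "dem.asc"
    births: str = "births.asc"
    facilities: str = "facilities.csv"
    roads: str | None = "roads.geojson"
    rivers: str | None = "rivers.geojson"
    boat_routes: str | None = "boat_routes.geojson"
    councils: str | None = "councils.geojson"
    scenarios: tuple[str, ...] = SCENARIO_IDS
    breaks: tuple[float, ...] = DEFAULT_BREAKS
    threshold_minutes: float = 120.0
    connectivity: int = 8
    tobler: ToblerParams = field(default_factory=ToblerParams)
    out_dir: str = "out"

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")
        if self.threshold_minutes != self.breaks[-1]:
            raise ValueError("threshold must equal the last zone break")


@dataclass
class AnalysisResult:
    surfaces: dict
    zones: dict
    catchments: dict
    reports: dict[str, CoverageReport]
    combo_map: object
    combined: ClassRaster


def run_analysis(
    combined: ClassRaster,
    dem: Dem,
    facilities: list[Facility],
    births: BirthRaster,
    councils: AdminUnits | None = None,
    scenarios: tuple[str, ...] = SCENARIO_IDS,
    breaks: tuple[float, ...] = DEFAULT_BREAKS,
    threshold_minutes: float = 120.0,
    config: EngineConfig = EngineConfig(),
    params: ToblerParams = ToblerParams(),
) -> AnalysisResult:
    """Travel-time surfaces, zones, catchments and coverage for each scenario
    plus the all-modes best case."""
    emonc = [f for f in facilities if f.is_emonc]
    if not emonc:
        raise ValueError("no EmONC facility among the inputs")
    sources = snap_facilities(emonc, combined).sources

    surfaces = {}
    for sid in scenarios:
        table = default_speed_table(sid)
        surfaces[sid] = accumulate_travel_time(
            combined, dem, table, sources, config, params
        )
    all_modes = all_modes_minimum(surfaces)
    combo = mode_combination_map(surfaces, threshold_minutes)

    everything = dict(surfaces)
    everything["all_modes"] = all_modes
    zones = {sid: classify_zones(s, breaks) for sid, s in everything.items()}
    catchments = {
        sid: two_hour_catchment(s, threshold_minutes)
        for sid, s in everything.items()
    }
    reports = {
        sid: build_report(everything[sid], zones[sid], births, councils,
                          threshold_minutes)
        for sid in everything
    }
    return AnalysisResult(everything, zones, catchments, reports, combo, combined)


def summary_dict(result: AnalysisResult) -> dict:
    """JSON-ready summary: zone tables per scenario, per-council poor access,
    and a dominance audit of the scenario ordering."""
    out: dict = {"scenarios": {}, "per_council_poor_access": {},
                 "dominance_audit": {}}
    for sid, rep in sorted(result.reports.items()):
        out["scenarios"][sid] = {
            "zones": {
                ZONE_LABELS[z]: {"births": c, "proportion": p}
                for z, (c, p) in rep.per_zone.items()
            },
            "poor_access_proportion": rep.poor_access_proportion,
        }
        out["per_council_poor_access"][sid] = rep.per_unit_poor
    poor = {sid: rep.poor_access_proportion
            for sid, rep in result.reports.items()}
    audit = {}
    if {"walking", "cycling"} <= poor.keys():
        audit["walking_ge_cycling"] = poor["walking"] >= poor["cycling"]
    if {"cycling", "motorcycle"} <= poor.keys():
        audit["cycling_ge_motorcycle"] = poor["cycling"] >= poor["motorcycle"]
    if {"walking", "car"} <= poor.keys():
        audit["walking_ge_car"] = poor["walking"] >= poor["car"]
    if "all_modes" in poor:
        audit["all_modes_le_every_single_mode"] = all(
            poor["all_modes"] <= v + 1e-12 for k, v in poor.items()
            if k != "all_modes"
        )
    out["dominance_audit"] = audit
    return out


def run_pipeline(cfg: RunConfig, in_dir: str | Path = ".") -> AnalysisResult:
    """File-driven pipeline run; writes all artifacts under ``cfg.out_dir``."""
    in_dir = Path(in_dir)

    def _p(name: str | None) -> Path | None:
        return None if name is None else in_dir / name

    base = read_raster(_p(cfg.landcover), "class")
    dem = read_raster(_p(cfg.dem), "dem")
    if dem.grid != base.grid:
        raise ValueError(
            f"stage build-surface: DEM grid {dem.grid} != land-cover grid "
            f"{base.grid} ({_p(cfg.dem)})"
        )
    births = read_raster(_p(cfg.births), "births")
    facilities = read_facilities_csv(_p(cfg.facilities))
    rivers = read_vector_layer(_p(cfg.rivers)) if cfg.rivers else None
    roads = read_vector_layer(_p(cfg.roads)) if cfg.roads else None
    boats = read_vector_layer(_p(cfg.boat_routes)) if cfg.boat_routes else None
    councils = read_admin_units(_p(cfg.councils)) if cfg.councils else None

    combined = build_combined_landcover(base, rivers, roads, boats)
    result = run_analysis(
        combined, dem, facilities, births, councils,
        scenarios=tuple(cfg.scenarios), breaks=tuple(cfg.breaks),
        threshold_minutes=cfg.threshold_minutes,
        config=EngineConfig(cfg.connectivity), params=cfg.tobler,
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster(combined, out / "combined_landcover.asc")
    for sid, surf in sorted(result.surfaces.items()):
        write_raster(surf, out / f"travel_time_{sid}.asc")
        write_ascii_grid(out / f"zones_{sid}.asc", surf.grid,
                         result.zones[sid].zone, -1, True)
        write_ascii_grid(out / f"catchment_{sid}.asc", surf.grid,
                         result.catchments[sid].inside.astype(np.int8), -1, True)
        _write_coverage_csv(result.reports[sid], out / f"coverage_{sid}.csv")
    write_ascii_grid(out / "mode_combinations.asc", combined.grid,
                     result.combo_map.bits, 255, True)

    summary = summary_dict(result)
    summary["provenance"] = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "n_facilities": len(facilities),
        "n_emonc": sum(1 for f in facilities if f.is_emonc),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return result


def _write_coverage_csv(rep: CoverageReport, path: Path) -> None:
    lines = ["zone,births,proportion"]
    for z in Zone:
        c, p = rep.per_zone[z]
        lines.append(f"{ZONE_LABELS[z]},{c!r},{p!r}")
    path.write_text("\n".join(lines) + "\n")


def _config_hash(cfg: RunConfig) -> str:
    d = asdict(cfg)
    d.pop("out_dir", None)  # hash the analysis config, not where it lands
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
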