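"""Travel scenarios: per-land-class transport modes, speeds, and the
anisotropic walking-speed correction.

Four scenarios are modelled after the primary transportation modes available
to women travelling to emergency obstetric care: walking, cycling,
motorcycle-taxi and car.  Every scenario also includes walking (for land
classes the vehicle cannot use) and boat travel on the lake corridor.
Wetlands, open water and rivers are impassable to every mode.

Walking speed is anisotropic: Tobler's exponential hiking function
``v ∝ exp(-k·|s + s0|)`` modulates the flat-terrain speed as a function of
the slope ``s`` in the direction of motion (fastest on a gentle downhill of
``-s0``).  Vehicle and boat speeds are isotropic; bicycle speed is kept
isotropic by default as well (an opt-in flag enables slope adjustment for
sensitivity analysis).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from accesscape.grid import LandClass, BARRIER_CLASSES, class_from_name


class TransportMode(enum.Enum):
    WALKING = "walking"
    BICYCLE = "bicycle"
    MOTORCYCLE = "motorcycle"
    CAR = "car"
    BOAT = "boat"

    @property
    def anisotropic(self) -> bool:
        return self is TransportMode.WALKING


SCENARIO_IDS = ("walking", "cycling", "motorcycle", "car")


@dataclass(frozen=True)
class SpeedEntry:
    """Mode and flat-terrain speed for one land class, or an impassable flag."""

    mode: TransportMode | None = None
    speed_kmh: float | None = None

    def __post_init__(self) -> None:
        if self.impassable:
            if self.mode is not None or self.speed_kmh is not None:
                raise ValueError("impassable entries carry no mode/speed")
        else:
            if self.mode is None or self.speed_kmh is None:
                raise ValueError("passable entries need both mode and speed")
            if not (math.isfinite(self.speed_kmh) and self.speed_kmh > 0):
                raise ValueError("speed must be finite and positive")

    @property
    def impassable(self) -> bool:
        return self.mode is None and self.speed_kmh is None

    @staticmethod
    def blocked() -> "SpeedEntry":
        return SpeedEntry()


IMPASSABLE = SpeedEntry.blocked()


@dataclass
class SpeedTable:
    """Scenario-specific mapping of land class to transport mode and speed."""

    scenario_id: str
    entries: dict[LandClass, SpeedEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c.name for c in LandClass if c not in self.entries]
        if missing:
            raise ValueError(f"speed table missing classes: {missing}")
        for cls in BARRIER_CLASSES:
            if not self.entries[cls].impassable:
                raise ValueError(f"{cls.name} must be impassable in every table")
        boat = self.entries[LandClass.BOAT_ROUTE]
        if boat.impassable or boat.mode is not TransportMode.BOAT:
            raise ValueError("boat_route must carry boat mode")

    def __getitem__(self, cls: LandClass) -> SpeedEntry:
        return self.entries[cls]


@dataclass(frozen=True)
class ToblerParams:
    """Parameters of the exponential slope-speed law for walking.

    ``steepness`` (k, default 3.5) and ``offset`` (s0, default 0.05) are the
    classic hiking-function constants.  With ``normalize_to_flat`` the factor
    is rescaled so flat ground gives exactly 1, i.e. table speeds are treated
    as flat-terrain speeds; switching it off uses the raw exponential
    (a uniform slowdown of exp(-k·s0) on flat ground).
    """

    steepness: float = 3.5
    offset: float = 0.05
    normalize_to_flat: bool = True
    bicycle_anisotropic: bool = False

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if not (0 <= self.offset < 1):
            raise ValueError("offset must lie in [0, 1)")


def tobler_multiplier(slope, params: ToblerParams = ToblerParams()):
    """Dimensionless walking-speed factor for a signed slope (rise/run).

    ``exp(-k·|s + s0|)``, divided by its flat-ground value when
    ``normalize_to_flat`` so the factor is exactly 1 at slope 0.  Accepts
    scalars or arrays.
    """
    s = np.asarray(slope, dtype=float)
    out = np.exp(-params.steepness * np.abs(s + params.offset))
    if params.normalize_to_flat:
        out = out / math.exp(-params.steepness * params.offset)
    if np.ndim(slope) == 0:
        return float(out)
    return out


def effective_speed(
    entry: SpeedEntry,
    slope: float,
    params: ToblerParams = ToblerParams(),
) -> float | None:
    """Slope-adjusted speed in km/h, or None when the entry is impassable.

    Only walking is adjusted (bicycle too when the opt-in flag is set);
    motorized and boat travel are isotropic.
    """
    if entry.impassable:
        return None
    adjust = entry.mode is TransportMode.WALKING or (
        params.bicycle_anisotropic and entry.mode is TransportMode.BICYCLE
    )
    if adjust:
        return entry.speed_kmh * tobler_multiplier(slope, params)
    return entry.speed_kmh


# ---------------------------------------------------------------------------
# default tables

_W = TransportMode.WALKING
_B = TransportMode.BICYCLE
_M = TransportMode.MOTORCYCLE
_C = TransportMode.CAR
_BOAT = TransportMode.BOAT

_DEFAULTS: dict[str, dict[LandClass, SpeedEntry]] = {
    "walking": {
        LandClass.FORESTLAND: SpeedEntry(_W, 1.0),
        LandClass.GRASSLAND: SpeedEntry(_W, 1.7),
        LandClass.CROPLAND: SpeedEntry(_W, 1.7),
        LandClass.SETTLEMENT: SpeedEntry(_W, 2.5),
        LandClass.WETLAND: IMPASSABLE,
        LandClass.OTHER_LAND: SpeedEntry(_W, 2.5),
        LandClass.RIVER_BARRIER: IMPASSABLE,
        LandClass.BOAT_ROUTE: SpeedEntry(_BOAT, 15.0),
        LandClass.MAJOR_ROAD: SpeedEntry(_W, 2.5),
        LandClass.MAJOR_ROAD_RESIDENTIAL: SpeedEntry(_W, 2.5),
        LandClass.SECONDARY_ROAD: SpeedEntry(_W, 2.5),
        LandClass.LOCAL_ROAD_ALL: SpeedEntry(_W, 2.5),
        LandClass.LOCAL_ROAD_MOTO_BIKE: SpeedEntry(_W, 2.5),
        LandClass.LOCAL_ROAD_WALK: SpeedEntry(_W, 2.5),
    },
    "cycling": {
        LandClass.FORESTLAND: SpeedEntry(_W, 1.0),
        LandClass.GRASSLAND: SpeedEntry(_B, 7.0),
        LandClass.CROPLAND: SpeedEntry(_W, 1.7),
        LandClass.SETTLEMENT: SpeedEntry(_B, 7.0),
        LandClass.WETLAND: IMPASSABLE,
        LandClass.OTHER_LAND: SpeedEntry(_B, 7.0),
        LandClass.RIVER_BARRIER: IMPASSABLE,
        LandClass.BOAT_ROUTE: SpeedEntry(_BOAT, 15.0),
        LandClass.MAJOR_ROAD: SpeedEntry(_B, 10.0),
        LandClass.MAJOR_ROAD_RESIDENTIAL: SpeedEntry(_B, 10.0),
        LandClass.SECONDARY_ROAD: SpeedEntry(_B, 10.0),
        LandClass.LOCAL_ROAD_ALL: SpeedEntry(_B, 10.0),
        LandClass.LOCAL_ROAD_MOTO_BIKE: SpeedEntry(_B, 10.0),
        LandClass.LOCAL_ROAD_WALK: SpeedEntry(_W, 2.5),
    },
    "motorcycle": {
        LandClass.FORESTLAND: SpeedEntry(_W, 1.0),
        LandClass.GRASSLAND: SpeedEntry(_M, 7.0),
        LandClass.CROPLAND: SpeedEntry(_W, 1.7),
        LandClass.SETTLEMENT: SpeedEntry(_M, 7.0),
        LandClass.WETLAND: IMPASSABLE,
        LandClass.OTHER_LAND: SpeedEntry(_M, 7.0),
        LandClass.RIVER_BARRIER: IMPASSABLE,
        LandClass.BOAT_ROUTE: SpeedEntry(_BOAT, 15.0),
        LandClass.MAJOR_ROAD: SpeedEntry(_M, 40.2),
        LandClass.MAJOR_ROAD_RESIDENTIAL: SpeedEntry(_M, 26.2),
        LandClass.SECONDARY_ROAD: SpeedEntry(_M, 35.2),
        LandClass.LOCAL_ROAD_ALL: SpeedEntry(_M, 15.0),
        LandClass.LOCAL_ROAD_MOTO_BIKE: SpeedEntry(_M, 15.0),
        LandClass.LOCAL_ROAD_WALK: SpeedEntry(_W, 2.5),
    },
    "car": {
        LandClass.FORESTLAND: SpeedEntry(_W, 1.0),
        LandClass.GRASSLAND: SpeedEntry(_W, 1.7),
        LandClass.CROPLAND: SpeedEntry(_W, 1.7),
        LandClass.SETTLEMENT: SpeedEntry(_W, 2.5),
        LandClass.WETLAND: IMPASSABLE,
        LandClass.OTHER_LAND: SpeedEntry(_W, 2.5),
        LandClass.RIVER_BARRIER: IMPASSABLE,
        LandClass.BOAT_ROUTE: SpeedEntry(_BOAT, 15.0),
        LandClass.MAJOR_ROAD: SpeedEntry(_C, 50.0),
        LandClass.MAJOR_ROAD_RESIDENTIAL: SpeedEntry(_C, 30.0),
        LandClass.SECONDARY_ROAD: SpeedEntry(_C, 40.0),
        LandClass.LOCAL_ROAD_ALL: SpeedEntry(_C, 15.0),
        LandClass.LOCAL_ROAD_MOTO_BIKE: SpeedEntry(_W, 2.5),
        LandClass.LOCAL_ROAD_WALK: SpeedEntry(_W, 2.5),
    },
}


def default_speed_table(scenario_id: str) -> SpeedTable:
    """The default mode/speed assignment for one of the four scenarios.

    Off-road classes fall back to walking where the scenario's vehicle cannot
    travel; the boat corridor is available at 15 km/h in every scenario;
    wetlands, open water and rivers are impassable throughout.
    """
    if scenario_id not in _DEFAULTS:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid: {', '.join(SCENARIO_IDS)}"
        )
    return SpeedTable(scenario_id, dict(_DEFAULTS[scenario_id]))


def default_speed_tables() -> dict[str, SpeedTable]:
    return {sid: default_speed_table(sid) for sid in SCENARIO_IDS}


# ---------------------------------------------------------------------------
# config (de)serialization


def speed_tables_to_yaml(tables: dict[str, SpeedTable]) -> str:
    """Serialize scenario speed tables to a YAML document (round-trip exact)."""
    doc: dict[str, dict[str, object]] = {}
    for sid, table in tables.items():
        block: dict[str, object] = {}
        for cls in LandClass:
            e = table[cls]
            if e.impassable:
                block[cls.name.lower()] = "impassable"
            else:
                block[cls.name.lower()] = {
                    "mode": e.mode.value,
                    "speed_kmh": e.speed_kmh,
                }
        doc[sid] = block
    return yaml.safe_dump(doc, sort_keys=True)


def speed_tables_from_yaml(text: str) -> dict[str, SpeedTable]:
    doc = yaml.safe_load(text)
    tables: dict[str, SpeedTable] = {}
    for sid, block in doc.items():
        entries: dict[LandClass, SpeedEntry] = {}
        for name, val in block.items():
            cls = class_from_name(name)
            if val == "impassable":
                entries[cls] = IMPASSABLE
            else:
                entries[cls] = SpeedEntry(
                    TransportMode(val["mode"]), float(val["speed_kmh"])
                )
        tables[sid] = SpeedTable(sid, entries)
    return tables
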