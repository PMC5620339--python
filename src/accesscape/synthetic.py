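"""Seeded generator of Kigoma-like synthetic landscapes.

Fabricates every input layer the accessibility pipeline needs — land cover,
DEM, roads, rivers, a lake with an offshore boat corridor and docks,
facilities, a live-birth raster and council polygons — with the broad
statistical structure of the study region: a land-cover mosaic with stated
areal fractions (grassland 34%, cropland 8%, forest 34%, water 14%, the
remainder settlements/other/wetland), elevations 800–2,400 m with highlands
toward the north and south and low ground along the western lake, a sparse
classified road network connecting settlement patches, rivers descending
from the highlands, births concentrated in settlements, and EmONC facilities
clustered in the largest towns.

Everything is deterministic per seed (a single PCG64 stream per stage, fixed
operation order).  The default grid is desk-scale: 300×300 cells of 100 m
(a 30 km × 30 km domain), chosen so the 2-hour reach of each travel mode
(walking ≈ 2–5 km, cycling ≈ 14 km off-road, motorized ≈ 30–80 km on roads)
interacts with facility spacing the way the real region's distances do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from accesscape.coverage import AdminUnits, BirthRaster
from accesscape.grid import (
    ClassRaster,
    Dem,
    Facility,
    Feature,
    GridSpec,
    LandClass,
    VectorLayer,
    build_combined_landcover,
)

_CRS = "synthetic-utm-like-meters"


@dataclass
class LandscapeParams:
    """Knobs of the synthetic region (defaults are the study-like conditions)."""

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(300, 300, cell_size=100.0,
                                         origin_x=0.0, origin_y=30_000.0,
                                         crs_label=_CRS)
    )
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "grassland": 0.34,
            "cropland": 0.08,
            "forestland": 0.34,
            "water": 0.14,
            "settlement": 0.04,
            "other_land": 0.04,
            "wetland": 0.02,
        }
    )
    elevation_range: tuple[float, float] = (800.0, 2400.0)
    n_towns: int = 14
    n_facilities_emonc: int = 11
    n_facilities_total: int = 127
    n_councils: int = 8
    road_density: float = 0.12  # km of road per km^2
    river_count: int = 3
    lake_on_west: bool = True
    boat_offset: float = 60.0  # meters offshore
    births_total: int = 83_000
    births_cell_size: float = 300.0
    settlement_birth_weight: float = 10.0
    correlation_length: float = 8.0  # cells, patch size of the random fields
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.class_fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be non-negative")
        if sum(fr.values()) > 1 + 1e-9:
            raise ValueError("class fractions must sum to at most 1")
        if self.n_facilities_emonc < 1:
            raise ValueError("need at least one EmONC facility")
        if self.boat_offset <= 0:
            raise ValueError("boat_offset must be positive")
        if self.settlement_birth_weight < 1:
            raise ValueError("settlement_birth_weight must be >= 1")
        if self.births_total <= 0:
            raise ValueError("births_total must be positive")


def kigoma_like_defaults() -> LandscapeParams:
    """Default parameters mirroring the study region's printed structure:
    land-cover fractions 34/8/34/14, elevations 800–2,400 m, 8 councils,
    11 EmONC facilities among 127 delivery sites, a western lake with a
    60 m offshore boat corridor."""
    return LandscapeParams()


@dataclass
class LandcoverResult:
    landcover: ClassRaster
    dem: Dem
    water_mask: np.ndarray
    shore_col: np.ndarray | None  # per-row first land column (lake variant)


@dataclass
class NetworkResult:
    roads: VectorLayer
    rivers: VectorLayer
    boat_routes: VectorLayer
    docks: VectorLayer
    towns: list[tuple[float, float]]  # world coords, largest patch first
    town_labels: np.ndarray  # labelled settlement patches (0 = none)


@dataclass
class SyntheticRegion:
    """A complete co-registered synthetic study region."""

    landcover: ClassRaster
    dem: Dem
    roads: VectorLayer
    rivers: VectorLayer
    boat_routes: VectorLayer
    facilities: list[Facility]
    births: BirthRaster
    councils: AdminUnits
    provenance: dict

    def combined_landcover(self) -> ClassRaster:
        return build_combined_landcover(
            self.landcover, self.rivers, self.roads, self.boat_routes
        )

    @property
    def emonc_facilities(self) -> list[Facility]:
        return [f for f in self.facilities if f.is_emonc]


def _rng(params: LandscapeParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed), stage])


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


# ---------------------------------------------------------------------------
# land cover + DEM


def generate_landcover(params: LandscapeParams) -> LandcoverResult:
    """Correlated-field land-cover mosaic and DEM, deterministic per seed.

    Class fractions are hit by quantile thresholding, so realized areal
    fractions match their targets to within rounding (comfortably inside a
    ±2-percentage-point band).  Wetlands occupy the lowest-lying land
    (drainage); the lake is a western strip with a noisy shoreline.
    """
    grid = params.grid
    rng = _rng(params, 0)
    n_rows, n_cols = grid.shape
    n = n_rows * n_cols
    fr = params.class_fractions

    # DEM: smooth noise + north/south highlands + rise away from the lake
    noise = _smooth_field(rng, grid.shape, params.correlation_length * 1.5)
    rprof = np.cos(2 * np.pi * np.arange(n_rows) / max(n_rows - 1, 1))[:, None]
    cprof = np.linspace(0.0, 1.0, n_cols)[None, :]
    z = noise + 1.1 * rprof + 0.9 * cprof
    e0, e1 = params.elevation_range
    elev = e0 + (z - z.min()) / (z.max() - z.min()) * (e1 - e0)
    dem = Dem(grid, elev)

    water = np.zeros(grid.shape, dtype=bool)
    shore_col: np.ndarray | None = None
    f_water = fr.get("water", 0.0)
    if f_water > 0:
        if params.lake_on_west:
            target = int(round(f_water * n))
            wiggle = ndimage.gaussian_filter1d(
                rng.standard_normal(n_rows), sigma=params.correlation_length * 2
            )
            wiggle = (wiggle - wiggle.mean()) / (wiggle.std() + 1e-12)
            wiggle *= 0.06 * n_cols

            def realized(base: float) -> np.ndarray:
                return np.clip(np.round(base + wiggle), 0, n_cols).astype(int)

            lo, hi = -0.1 * n_cols, 1.1 * n_cols
            for _ in range(60):
                mid = (lo + hi) / 2
                if realized(mid).sum() < target:
                    lo = mid
                else:
                    hi = mid
            shore_col = realized(hi)
            for r in range(n_rows):
                water[r, : shore_col[r]] = True
        else:
            wfield = _smooth_field(rng, grid.shape, params.correlation_length)
            thr = np.quantile(wfield, f_water)
            water = wfield <= thr

    land = ~water
    # water is coded with the wetland barrier class (impassable open water)
    codes = np.full(grid.shape, int(LandClass.WETLAND), dtype=np.int16)

    # wetlands: lowest-lying land cells (drainage)
    n_wet = int(round(fr.get("wetland", 0.0) * n))
    is_wet = np.zeros(grid.shape, dtype=bool)
    if n_wet > 0:
        land_elev = np.where(land, elev, np.inf)
        order = np.argsort(land_elev, axis=None, kind="stable")
        wet_idx = order[:n_wet]
        is_wet.ravel()[wet_idx] = True

    # settlements: disks around town centers on dry land
    dry = land & ~is_wet
    n_set = int(round(fr.get("settlement", 0.0) * n))
    is_set = _place_settlements(params, rng, dry, elev, n_set)

    # remaining cover classes by quantiles of an independent correlated field
    remaining = dry & ~is_set
    g = _smooth_field(rng, grid.shape, params.correlation_length)
    rem_idx = np.flatnonzero(remaining.ravel())
    order = rem_idx[np.argsort(g.ravel()[rem_idx], kind="stable")]
    n_forest = int(round(fr.get("forestland", 0.0) * n))
    n_grass = int(round(fr.get("grassland", 0.0) * n))
    n_crop = int(round(fr.get("cropland", 0.0) * n))
    if n_forest + n_grass + n_crop > order.size:
        raise ValueError("class fractions leave too few cells for cover classes")
    flat = codes.ravel()
    flat[order[:n_forest]] = int(LandClass.FORESTLAND)
    flat[order[n_forest : n_forest + n_grass]] = int(LandClass.GRASSLAND)
    flat[order[n_forest + n_grass : n_forest + n_grass + n_crop]] = int(
        LandClass.CROPLAND
    )
    flat[order[n_forest + n_grass + n_crop :]] = int(LandClass.OTHER_LAND)
    codes[is_set] = int(LandClass.SETTLEMENT)
    # water and wetland cells keep the barrier code

    return LandcoverResult(ClassRaster(grid, codes), dem, water, shore_col)


def _place_settlements(params, rng, dry, elev, n_target) -> np.ndarray:
    """Settlement disks around low-elevation town centers with min separation."""
    grid = params.grid
    is_set = np.zeros(grid.shape, dtype=bool)
    if n_target <= 0:
        return is_set
    dry_idx = np.flatnonzero(dry.ravel())
    if dry_idx.size == 0:
        return is_set
    e = elev.ravel()[dry_idx]
    w = np.exp(-(e - e.min()) / (0.3 * (e.max() - e.min()) + 1e-9))
    w /= w.sum()
    n_cand = min(dry_idx.size, params.n_towns * 30)
    cand = rng.choice(dry_idx, size=n_cand, replace=False, p=w)
    min_sep = 0.18 * min(grid.n_rows, grid.n_cols)
    centers: list[tuple[int, int]] = []
    for flat in cand:
        r, c = divmod(int(flat), grid.n_cols)
        if all(math.hypot(r - r0, c - c0) >= min_sep for r0, c0 in centers):
            centers.append((r, c))
        if len(centers) == params.n_towns:
            break
    if not centers:
        centers = [divmod(int(cand[0]), grid.n_cols)]

    # disk areas ~ Zipf-like so the first towns are the big ones
    k = len(centers)
    wts = 1.0 / (np.arange(k) + 1.0) ** 0.7
    areas = n_target * wts / wts.sum()
    rr, cc = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    for (r0, c0), a in zip(centers, areas):
        rad = max(1.0, math.sqrt(a / math.pi))
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        is_set |= disk & dry
    return is_set


# ---------------------------------------------------------------------------
# roads, rivers, boat routes


def generate_network(
    params: LandscapeParams,
    landcover: ClassRaster,
    dem: Dem,
    water_mask: np.ndarray | None = None,
    shore_col: np.ndarray | None = None,
) -> NetworkResult:
    """Roads over a town spanning tree, descending rivers, lake boat corridor.

    Towns are the connected settlement patches (largest first).  The road
    graph is the Euclidean minimum spanning tree over town centers plus the
    shortest extra links up to the ``road_density`` budget; edges are classed
    major/secondary/local by betweenness rank, and local roads are further
    split into car-, motorcycle/bicycle- and walking-only categories.
    Rivers follow steepest descent from highland cells until they reach
    water or a pit, so their vertex elevations strictly decrease.  The boat
    route runs ``boat_offset`` meters offshore, and docks tie shoreline
    towns to it.
    """
    import networkx as nx

    grid = landcover.grid
    rng = _rng(params, 1)
    settlement = landcover.values == int(LandClass.SETTLEMENT)
    labels, n_patch = ndimage.label(settlement, structure=np.ones((3, 3)))
    if n_patch == 0:
        raise ValueError(
            "no settlement patches; increase the settlement fraction"
        )
    sizes = ndimage.sum_labels(settlement, labels, index=np.arange(1, n_patch + 1))
    order = np.argsort(-sizes, kind="stable")
    centroids = ndimage.center_of_mass(settlement, labels,
                                       index=np.arange(1, n_patch + 1))
    towns: list[tuple[float, float]] = []
    town_cells: list[tuple[int, int]] = []
    for i in order:
        r, c = centroids[i]
        # snap centroid to the nearest cell of its own patch
        patch = np.argwhere(labels == i + 1)
        d2 = (patch[:, 0] - r) ** 2 + (patch[:, 1] - c) ** 2
        rr, cc = patch[int(np.argmin(d2))]
        town_cells.append((int(rr), int(cc)))
        towns.append(grid.cell_center(int(rr), int(cc)))

    # --- roads
    road_feats: list[Feature] = []
    if len(towns) >= 2:
        g = nx.Graph()
        for i, p in enumerate(towns):
            g.add_node(i, pos=p)
        pts = np.array(towns)
        full = [
            (i, j, float(np.hypot(*(pts[i] - pts[j]))))
            for i in range(len(towns))
            for j in range(i + 1, len(towns))
        ]
        full_g = nx.Graph()
        full_g.add_weighted_edges_from(full)
        mst = nx.minimum_spanning_tree(full_g, weight="weight")
        g.add_weighted_edges_from(
            (u, v, d["weight"]) for u, v, d in mst.edges(data=True)
        )
        budget_m = params.road_density * (grid.width_m / 1000.0) * (
            grid.height_m / 1000.0
        ) * 1000.0
        total = sum(d["weight"] for _, _, d in g.edges(data=True))
        extras = sorted(
            (e for e in full if not g.has_edge(e[0], e[1])), key=lambda e: e[2]
        )
        for u, v, w in extras:
            if total + w > budget_m:
                break
            g.add_edge(u, v, weight=w)
            total += w

        btw = nx.edge_betweenness_centrality(g, weight="weight")
        ranked = sorted(
            g.edges(), key=lambda e: (-btw[tuple(sorted(e))], tuple(sorted(e)))
        )
        m = len(ranked)
        n_major = max(1, int(round(0.2 * m)))
        n_sec = int(round(0.3 * m))
        local_cycle = (
            LandClass.LOCAL_ROAD_ALL,
            LandClass.LOCAL_ROAD_MOTO_BIKE,
            LandClass.LOCAL_ROAD_WALK,
        )
        li = 0
        for rank, (u, v) in enumerate(ranked):
            if rank < n_major:
                cls = LandClass.MAJOR_ROAD
            elif rank < n_major + n_sec:
                cls = LandClass.SECONDARY_ROAD
            else:
                cls = local_cycle[li % 3]
                li += 1
            road_feats.append(Feature(LineString([towns[u], towns[v]]), cls))
    roads = VectorLayer("polyline", road_feats, crs_label=grid.crs_label)

    # --- rivers
    river_feats: list[Feature] = []
    if params.river_count > 0:
        elev = dem.elevation
        land = landcover.values != int(LandClass.WETLAND)
        if water_mask is not None:
            land &= ~water_mask
        land_elev = np.where(land, elev, -np.inf)
        hi_thr = np.quantile(elev[land], 0.95) if land.any() else elev.max()
        starts_pool = np.argwhere(land_elev >= hi_thr)
        starts: list[tuple[int, int]] = []
        if starts_pool.size:
            perm = rng.permutation(len(starts_pool))
            min_sep = 0.2 * min(grid.n_rows, grid.n_cols)
            for k in perm:
                r, c = map(int, starts_pool[k])
                if all(math.hypot(r - r0, c - c0) >= min_sep for r0, c0 in starts):
                    starts.append((r, c))
                if len(starts) == params.river_count:
                    break
        for r0, c0 in starts:
            path = _descend(elev, (r0, c0),
                            water_mask if water_mask is not None else
                            np.zeros(grid.shape, bool))
            if len(path) >= 2:
                coords = [grid.cell_center(r, c) for r, c in path]
                river_feats.append(
                    Feature(LineString(coords), LandClass.RIVER_BARRIER)
                )
    rivers = VectorLayer("polyline", river_feats, crs_label=grid.crs_label)

    # --- boat corridor + docks
    boat_feats: list[Feature] = []
    dock_feats: list[Feature] = []
    if (
        params.lake_on_west
        and water_mask is not None
        and shore_col is not None
        and water_mask.any()
    ):
        cs = grid.cell_size
        off = params.boat_offset
        verts = []
        for r in range(grid.n_rows):
            shore_x = grid.origin_x + shore_col[r] * cs
            xb = shore_x - off
            if xb > grid.origin_x + cs / 2 and shore_col[r] > 0:
                _, y = grid.cell_center(r, 0)
                verts.append((xb, y))
        if len(verts) >= 2:
            boat_feats.append(Feature(LineString(verts), LandClass.BOAT_ROUTE))
            boat_line = LineString(verts)
            # docks: connect shoreline towns to the corridor
            shore_d = []
            for t, (tx, ty) in enumerate(towns):
                row = min(
                    grid.n_rows - 1,
                    max(0, int((grid.origin_y - ty) / cs)),
                )
                shore_x = grid.origin_x + shore_col[row] * cs
                shore_d.append((tx - shore_x, t))
            shore_d.sort()
            dock_range = 0.15 * grid.width_m
            chosen = [t for d, t in shore_d if d <= dock_range] or (
                [shore_d[0][1]] if shore_d else []
            )
            for t in chosen:
                p = Point(towns[t])
                q = boat_line.interpolate(boat_line.project(p))
                dock_feats.append(
                    Feature(LineString([towns[t], (q.x, q.y)]),
                            LandClass.BOAT_ROUTE)
                )
    boat_routes = VectorLayer(
        "polyline", boat_feats + dock_feats, crs_label=grid.crs_label
    )
    docks = VectorLayer("polyline", dock_feats, crs_label=grid.crs_label)

    return NetworkResult(roads, rivers, boat_routes, docks, towns, labels)


def _descend(elev: np.ndarray, start: tuple[int, int],
             water: np.ndarray) -> list[tuple[int, int]]:
    """Steepest-descent path; stops at water or a pit.  Strictly decreasing."""
    n_rows, n_cols = elev.shape
    path = [start]
    r, c = start
    for _ in range(n_rows * n_cols):
        best = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                if elev[rr, cc] < elev[r, c] and (
                    best is None or elev[rr, cc] < elev[best]
                ):
                    best = (rr, cc)
        if best is None:
            break
        path.append(best)
        r, c = best
        if water[r, c]:
            break
    return path


# ---------------------------------------------------------------------------
# facilities, births, councils


def generate_population(
    params: LandscapeParams,
    landcover: ClassRaster,
    network: NetworkResult,
) -> tuple[list[Facility], BirthRaster, AdminUnits]:
    """Facilities in towns, births concentrated in settlements, Voronoi councils.

    EmONC facilities occupy the largest towns (a CEmONC / CEmONC-1 / BEmONC-1
    mix in 8:1:2 proportions); the remaining delivery sites scatter over the
    smaller towns.  Births are allocated to non-water cells with a
    multiplicative settlement weight using deterministic largest-remainder
    rounding, so they are whole numbers summing exactly to ``births_total``,
    then aggregated onto the coarser birth grid.  Councils are the Voronoi
    cells of the first ``n_councils`` towns, clipped to the region.
    """
    grid = landcover.grid
    rng = _rng(params, 2)
    towns = network.towns
    labels = network.town_labels
    settlement = landcover.values == int(LandClass.SETTLEMENT)

    # --- facilities
    n_em = params.n_facilities_emonc
    n1 = max(1, int(round(n_em * 8 / 11)))
    n3 = int(round(n_em * 2 / 11))
    n2 = max(0, n_em - n1 - n3)
    levels = ["CEmONC"] * n1 + ["CEmONC_minus_1"] * n2 + ["BEmONC_minus_1"] * n3
    levels = levels[:n_em]

    used_cells: set[tuple[int, int]] = set()

    def place_in_town(t: int) -> tuple[float, float]:
        # a settlement cell of town t's patch, nearest its center, unused
        r0, c0 = grid.world_to_cell(*towns[t])
        lab = labels[min(r0, grid.n_rows - 1), min(c0, grid.n_cols - 1)]
        patch = np.argwhere(labels == lab) if lab > 0 else np.argwhere(settlement)
        d2 = (patch[:, 0] - r0) ** 2 + (patch[:, 1] - c0) ** 2
        for k in np.argsort(d2, kind="stable"):
            cell = (int(patch[k, 0]), int(patch[k, 1]))
            if cell not in used_cells:
                used_cells.add(cell)
                return grid.cell_center(*cell)
        return towns[t]

    facilities: list[Facility] = []
    n_towns = len(towns)
    for i, lvl in enumerate(levels):
        x, y = place_in_town(i % n_towns)
        facilities.append(Facility(f"emonc_{i + 1:03d}", x, y, lvl))
    n_rest = max(0, params.n_facilities_total - n_em)
    for j in range(n_rest):
        t = n_towns - 1 - (j % n_towns)  # smaller towns first
        x, y = place_in_town(t)
        facilities.append(Facility(f"site_{j + 1:03d}", x, y, "non_EmONC"))

    # --- births (integer largest-remainder allocation on the analysis grid)
    barrier = np.isin(
        landcover.values,
        [int(LandClass.WETLAND), int(LandClass.RIVER_BARRIER)],
    )
    w = np.where(barrier, 0.0, 1.0)
    w[settlement] *= params.settlement_birth_weight
    wflat = w.ravel()
    p = wflat / wflat.sum() * params.births_total
    alloc = np.floor(p)
    shortfall = int(round(params.births_total - alloc.sum()))
    if shortfall > 0:
        frac = p - alloc
        top = np.argsort(-frac, kind="stable")[:shortfall]
        alloc[top] += 1
    fine = alloc.reshape(grid.shape)

    bcell = params.births_cell_size
    nb_rows = int(math.ceil(grid.height_m / bcell))
    nb_cols = int(math.ceil(grid.width_m / bcell))
    bgrid = GridSpec(nb_rows, nb_cols, bcell, grid.origin_x, grid.origin_y,
                     grid.crs_label)
    xs, ys = grid.cell_centers()
    brows, bcols = bgrid.world_to_cell_arrays(xs.ravel(), ys.ravel())
    flat_idx = brows * nb_cols + bcols
    agg = np.bincount(flat_idx, weights=fine.ravel(),
                      minlength=nb_rows * nb_cols)
    births = BirthRaster(bgrid, agg.reshape(nb_rows, nb_cols))

    # --- councils
    n_c = params.n_councils
    seeds = list(towns[:n_c])
    dry_idx = np.flatnonzero(~barrier.ravel())
    while len(seeds) < n_c and dry_idx.size:
        flat = int(rng.choice(dry_idx))
        seeds.append(grid.cell_center(*divmod(flat, grid.n_cols)))
    bbox = box(*grid.bounds)
    cells = voronoi_diagram(MultiPoint([Point(s) for s in seeds]), envelope=bbox)
    polys = [None] * len(seeds)
    for geom in cells.geoms:
        clipped = geom.intersection(bbox)
        for i, s in enumerate(seeds):
            if polys[i] is None and clipped.covers(Point(s)):
                polys[i] = clipped
                break
    units = AdminUnits(
        names=[f"council_{i + 1:02d}" for i in range(len(seeds))],
        polygons=[p if p is not None else bbox for p in polys],
    )
    return facilities, births, units


def generate_region(params: LandscapeParams | None = None) -> SyntheticRegion:
    """End-to-end synthetic region build (land cover → network → population)."""
    if params is None:
        params = kigoma_like_defaults()
    lc = generate_landcover(params)
    net = generate_network(params, lc.landcover, lc.dem, lc.water_mask,
                           lc.shore_col)
    facilities, births, councils = generate_population(params, lc.landcover, net)
    prov = {"seed": params.seed, "params": _params_dict(params)}
    return SyntheticRegion(
        landcover=lc.landcover,
        dem=lc.dem,
        roads=net.roads,
        rivers=net.rivers,
        boat_routes=net.boat_routes,
        facilities=facilities,
        births=births,
        councils=councils,
        provenance=prov,
    )


def _params_dict(params: LandscapeParams) -> dict:
    d = asdict(params)
    d["grid"] = asdict(params.grid) if not isinstance(d["grid"], dict) else d["grid"]
    return d
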