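# Methods

## Problem and model

The package estimates geographic accessibility of emergency obstetric and
neonatal care (EmONC) as the minimum travel time from every location in a
region to its nearest EmONC facility, using a raster least-cost (friction
surface) model. Each cell of a combined land-cover raster carries a class —
six cover classes (forestland, grassland, cropland, settlement, wetland,
other land), six road classes (major; major through residential areas;
secondary; and local roads passable to cars, to motorcycles/bicycles, or on
foot only), and a boat corridor — and each travel scenario assigns every
class a transport mode and a speed. Wetlands, open water and rivers are
impassable to every mode.

Four scenarios reflect the primary means of transport available to women
travelling to delivery care: walking, cycling, motorcycle-taxi and car.
Every scenario also includes walking (for classes the vehicle cannot use)
and boat travel at 15 km/h on the lake corridor. The flat-terrain speeds per
class are fixed constants of the model (e.g. walking 1.0 km/h in forest,
1.7 km/h on grassland/cropland, 2.5 km/h in settlements and on roads;
bicycle 7 off-road and 10 on roads; motorcycle 40.2/26.2/35.2/15 on the
road hierarchy; car 50/30/40/15), shipped as a YAML-serializable speed
table. An *all-modes* scenario is the cell-wise minimum over the four.

### Anisotropic walking

Walking speed depends on the slope *s* (rise over run, signed in the
direction of motion) through the exponential hiking law

    v(s) = v_flat · exp(−k·|s + s₀|) / exp(−k·s₀),   k = 3.5, s₀ = 0.05,

so the factor is exactly 1 on flat ground, peaks at a gentle downhill of
−s₀, and decays symmetrically about it. The normalization treats the table
speeds as flat-terrain speeds; a `normalize_to_flat=False` switch uses the
raw exponential instead (a uniform slowdown of exp(−k·s₀) ≈ 0.84 on flat
ground), since cost-surface tools differ on this point. Motorized and boat
travel are isotropic. Bicycle travel is also isotropic **by default**,
mirroring a documented limitation of the accessibility software this
workflow models; `bicycle_anisotropic=True` enables the slope law for
bicycles as a sensitivity analysis.

### Least-cost accumulation

Adjacent cells are connected with 8-connectivity (queen moves) by default;
16-connectivity (adding knight moves) is available and reduces the
worst-case grid-metric distortion from 1/cos(π/8) − 1 ≈ 8.24% to ≈ 2.8%.
One step from cell *a* to adjacent cell *b* costs

    t(a→b) = d/2 · (1/v_a(s) + 1/v_b(s))   minutes,

with *d* the center distance and both effective speeds evaluated at the
slope of the step in the direction of travel. Travel direction is toward
the facility; propagation runs outward from all facility source cells over
the reversed arc set, which is exactly equivalent. The solver is a pure
multi-source Dijkstra (scipy sparse-graph implementation) with a total
ordering and no randomness; an independent oracle builds the explicit
weighted digraph and runs networkx's textbook shortest path, and the two
are required to agree to ≤1e-9 relative on randomized instances.

Numerical/degenerate-input conventions:

* a diagonal step is forbidden when both orthogonally shared cells are
  barriers (no squeezing between barrier corners); a knight step requires
  both crossed cells passable;
* unreachable cells carry an explicit boolean flag in the data model
  (serialized as nodata; +inf is used internally for arithmetic);
* facilities falling on a barrier cell (a rasterization artifact) snap to
  the nearest passable cell within 10 cells, deterministically (distance,
  then row, then col), and the snap is logged; several facilities in one
  cell collapse to one source;
* rasterization of polylines uses a fixed center-within-half-cell rule,
  polygons a center-covered rule, both deterministic.

### Combined land cover

The combined raster is built by burning, in order, rivers (an internal
`river_barrier` code kept distinct from wetland for provenance, identical
in behaviour), then roads (their class), then boat corridors over the base
cover. Later burns win, so a road crossing a river remains passable —
implicit bridge semantics, without which the road network would
disintegrate at every crossing. Major-road cells whose base cover is
settlement are recoded as "major road through residential area". Open
water (the lake) uses the wetland barrier code: both are impassable
everywhere and the boat corridor is burned on top.

## Zones, catchments, coverage

Good access is a travel time **at or under 120 minutes**; the boundary is
closed, so exactly 120 is good access. Surfaces are banded into 0–30,
31–60, 61–90, 91–120 and >120 minute zones (closed upper bounds;
unreachable cells fall in the last band). The mode-combination map records,
per cell, the subset of scenarios reaching care within 2 hours.

Birth coverage statistics never resample the birth raster (typically
coarser than the analysis grid): each birth cell is assigned to the zone,
catchment or council containing its center, so zonal counts conserve the
raster total exactly. The allocation of synthetic births is integer-valued
(largest-remainder rounding), which makes the conservation identity exact
in floating point as well. Per-council poor-access proportions are reported
as missing (not zero) for councils without births. Zones can optionally be
polygonized (exact raster→polygon→raster round trip on the same grid) for
workflows that aggregate over polygons; direct raster zonal statistics are
the default and avoid the polygon border error.

The expected number of births in a catchment is the product
`women_pop × growth_coeff × fertility_rate × proportion`; the three
demographic factors are user inputs (the fertility factor is a single
births-per-woman-per-year scalar — upstream sources are ambiguous about
its exact construction, so it is deliberately exposed as one knob).

Upgrade ranking scores each non-EmONC candidate by the births newly
covered when its 2-hour catchment joins the union of existing catchments —
operationalizing "prioritize facilities in areas of poor estimated access
and high birth density". Coverage of a union is submodular, so greedy
selection has non-increasing gains; ties break by facility id.

## Synthetic landscape generator

The generator fabricates the full input stack so the pipeline is testable
offline. It emulates the study region's printed structure:

* land-cover fractions grassland 0.34, cropland 0.08, forestland 0.34,
  water 0.14, and the remainder split settlement 0.04 / other 0.04 /
  wetland 0.02 (wetland is carved from the lowest-lying land to mimic
  drainage; the split of the unstated remainder is our choice);
* elevations spanning exactly 800–2,400 m, highlands toward the north and
  south edges and low ground along the western lake;
* a lake occupying the west with a noisy shoreline, a boat corridor 60 m
  offshore and dock links to shoreline towns;
* a sparse road network: Euclidean minimum spanning tree over settlement
  patches plus extra links up to a `road_density` budget (0.12 km/km²),
  classed major/secondary/local by edge betweenness, local roads split
  into car / motorcycle-bicycle / walking-only;
* rivers descending by steepest descent from highland cells (strictly
  decreasing vertex elevations) until they reach water;
* 127 delivery sites of which 11 are EmONC (8 CEmONC, 1 CEmONC-1,
  2 BEmONC-1), EmONC in the largest towns;
* 83,000 expected live births allocated to non-water cells with a ×10
  multiplicative weight on settlements, aggregated to a coarser birth grid
  (300 m cells); 8 councils as the Voronoi partition of the largest towns.

Land-cover classes are assigned by quantile-thresholding correlated
Gaussian fields (Gaussian-filtered white noise, correlation length 8
cells), so classes form contiguous patches and realized fractions hit
their targets to within rounding. All randomness flows from one seed
through per-stage PCG64 streams in a fixed order, so regions are bitwise
reproducible.

**Scale.** The default grid is 300×300 cells of **100 m** (30 km × 30 km).
A desk-scale domain cannot keep both the real region's extent and its 30 m
resolution; we keep the *interaction* between mode reach and facility
spacing instead: with ~11 EmONC facilities over 900 km², walking (2-hour
reach ≈ 2–5 km) leaves most births with poor access, cycling (≈ 14 km
off-road, less through forest) covers much more, and motorized modes
extend along the road network — reproducing the study-type ordering
walking > cycling > motorcycle of poor-access proportions, with the
all-modes share below every single mode. The birth raster uses 300 m cells
so the cross-resolution center-assignment path is exercised by default.

**What passing tests do not show.** The generator does not calibrate
against real land-cover, road or population rasters: patch shapes are
Gaussian-field artifacts, roads are straight town-to-town links, births
are a two-level (settlement vs open land) intensity, and absolute
poor-access percentages depend on these choices. Tests therefore establish
correctness of the machinery and the *qualitative* scenario structure, not
the real region's published percentages, which derive from
version-dependent external datasets.

## Analysis problem sizes

The numbered drivers under `analysis/` and the acceptance script run on the
default 300×300 region (≈0.3 s generation, ≈1 s for all five surfaces);
oracle-equivalence audits use 40×40 mosaics, where the explicit-graph
reference is fast. These sizes are the package's chosen defaults for a
reproducible desk-scale study.

## Known limitations

* Single dry-season speed tables; no seasonal, stochastic or congestion
  effects.
* No graph-on-road network routing; all movement is cell-based, so
  travel-time error includes the grid-metric distortion (≤8.24% at
  8-connectivity on uniform terrain).
* The exact edge composition and connectivity of the modelled desktop
  accessibility software are not published; numeric replication of its
  output is not claimed (both of our documented conventions are exact and
  testable instead).
* Birth rasters are treated as error-free intensities; no uncertainty
  propagation.
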