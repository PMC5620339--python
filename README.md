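# accesscape

Raster travel-time accessibility modelling of emergency obstetric and
neonatal care (EmONC), for epidemiologists and health planners who need to
know **what share of births can reach lifesaving delivery care within two
hours, and where transport or facility upgrades would help most**.

The core is a least-cost (friction surface) travel-time model. A combined
land-cover raster (cover classes, a classified road hierarchy, impassable
wetlands/rivers, a lake boat corridor) and a DEM define, per travel
scenario *m* ∈ {walking, cycling, motorcycle, car}, an effective speed
v<sub>c</sub>(s) for each cell class *c* and slope *s*. Walking is
anisotropic via the exponential hiking law

&nbsp;&nbsp;&nbsp;&nbsp;v(s) = v_flat · e^(−3.5·|s + 0.05|) / e^(−0.175)

(fastest on a gentle downhill), vehicles and boats are isotropic. The
minimum travel time from every cell to the nearest EmONC facility,

&nbsp;&nbsp;&nbsp;&nbsp;T_m(x) = min over facilities f, paths x→f of Σ d/2·(1/v_from + 1/v_to),

is computed by exact multi-source Dijkstra over the grid graph, banded into
30-minute zones (good access ≡ T ≤ 120 min), and intersected with a gridded
live-birth raster to report the proportion of births with poor access —
regionally, per 30-minute zone, per administrative council, per scenario,
and under the all-modes best case min_m T_m. A greedy coverage maximizer
ranks non-EmONC facilities by the births an upgrade would newly cover. A
seeded synthetic landscape generator (land cover, DEM, roads, rivers, lake
with boat corridor and docks, facilities, births, councils) makes the whole
pipeline runnable and testable with no external data.

## Worked example

```python
import accesscape as ac
from accesscape.pipeline import run_analysis

region = ac.generate_region(ac.LandscapeParams(seed=0))   # 300x300, 100 m cells
result = run_analysis(region.combined_landcover(), region.dem,
                      region.facilities, region.births, region.councils)
for sid, rep in sorted(result.reports.items()):
    print(f"{sid:11s} poor access: {100 * rep.poor_access_proportion:5.1f}% of births")
```

prints

```
all_modes   poor access:   3.9% of births
car         poor access:  30.6% of births
cycling     poor access:   4.6% of births
motorcycle  poor access:   3.9% of births
walking     poor access:  50.6% of births
```

i.e. on this synthetic region half of births are more than two hours' walk
from EmONC care; bicycles and motorcycles collapse that to a few percent,
cars help less off-road (they fall back to walking speed off the road
network), and even with every mode available 3.9% of births remain beyond
two hours — the share only facility upgrades can reach. The numbered
scripts under `analysis/` (simulate → surfaces → zones/catchments → birth
coverage → upgrade ranking) run the same study step by step and write their
tables under `results/`; large rasters go to `scratch/`. A CLI mirrors the
stages: `accesscape simulate | build-surface | travel-time | catchments |
coverage | rank-upgrades | run`.

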