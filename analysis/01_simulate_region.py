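"""Generate the default synthetic study region and write its input layers.

Produces a 30 km x 30 km, 300x300-cell landscape (grassland/cropland/forest/
water in the 34/8/34/14 mix, lake on the west with a 60 m offshore boat
corridor, 3 rivers, 8 councils, 127 delivery sites of which 11 offer EmONC,
83,000 expected live births concentrated in settlements) and reports its
realized composition.

Layers land in scratch/region/ (large rasters); the composition table in
results/01_region_summary.json.
"""

import json
import sys
from pathlib import Path

import accesscape as ac
from accesscape.cli import write_region
from accesscape.grid import LandClass

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    region = ac.generate_region(ac.LandscapeParams(seed=seed))
    out = ROOT / "scratch" / "region"
    write_region(region, out)

    v = region.landcover.values
    summary = {
        "seed": seed,
        "grid": {"shape": list(region.landcover.grid.shape),
                 "cell_size_m": region.landcover.grid.cell_size},
        "realized_class_fractions": {
            c.name.lower(): round(float((v == int(c)).mean()), 4)
            for c in LandClass
            if (v == int(c)).any()
        },
        "n_facilities": len(region.facilities),
        "n_emonc": len(region.emonc_facilities),
        "births_total": region.births.total,
        "n_councils": len(region.councils.names),
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "01_region_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    print(f"region written to {out}")
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
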