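"""Birth coverage: who can reach emergency obstetric care within two hours?

Aggregates the live-birth raster over the travel-time zones of every
scenario (the regional table) and computes, per administrative council, the
proportion of births with poor access (> 2 h) under each scenario including
the all-modes best case — the decision table for targeting transport
interventions versus facility upgrades.

Writes results/04_zone_births.csv and results/04_council_poor_access.csv.
"""

import sys
from pathlib import Path

import accesscape as ac
from accesscape.catchments import ZONE_LABELS, Zone
from accesscape.pipeline import run_analysis

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    region = ac.generate_region(ac.LandscapeParams(seed=seed))
    res = run_analysis(region.combined_landcover(), region.dem,
                       region.facilities, region.births, region.councils)

    lines = ["scenario,zone,births,pct"]
    for sid, rep in sorted(res.reports.items()):
        for z in Zone:
            c, p = rep.per_zone[z]
            lines.append(f"{sid},{ZONE_LABELS[z]},{c:.0f},{100 * p:.1f}")
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "04_zone_births.csv").write_text(
        "\n".join(lines) + "\n")

    sids = sorted(res.reports)
    rows = ["council," + ",".join(sids)]
    for name in region.councils.names:
        vals = []
        for sid in sids:
            v = res.reports[sid].per_unit_poor.get(name)
            vals.append("" if v is None else f"{100 * v:.1f}")
        rows.append(f"{name}," + ",".join(vals))
    (ROOT / "results" / "04_council_poor_access.csv").write_text(
        "\n".join(rows) + "\n")

    poor = {sid: res.reports[sid].poor_access_proportion for sid in sids}
    print("regional poor-access (% of births):",
          {k: round(100 * v, 1) for k, v in poor.items()})
    print("\n".join(rows))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
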