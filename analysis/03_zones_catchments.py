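"""Classify surfaces into 30-minute zones and map transport-mode combinations.

Bands each scenario's surface into 0-30 / 31-60 / 61-90 / 91-120 / >120
minute zones, and builds the mode-combination map: for every cell, which of
the four scenarios reach EmONC care within 2 hours.  A quicklook figure of
the all-modes zones goes to scratch/figures/.

Writes results/03_zone_areas.csv (areal shares) and
results/03_mode_combinations.csv (areal share per mode subset).
"""

import sys
from pathlib import Path

import accesscape as ac
from accesscape.catchments import ZONE_LABELS, Zone, mode_combination_map
from accesscape.pipeline import run_analysis

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    region = ac.generate_region(ac.LandscapeParams(seed=seed))
    res = run_analysis(region.combined_landcover(), region.dem,
                       region.facilities, region.births, region.councils)
    n = region.landcover.values.size

    lines = ["scenario," + ",".join(ZONE_LABELS[z] for z in Zone)]
    for sid, zr in sorted(res.zones.items()):
        counts = zr.counts()
        lines.append(sid + "," + ",".join(
            f"{100 * counts[z] / n:.2f}" for z in Zone))
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "03_zone_areas.csv").write_text(
        "\n".join(lines) + "\n")
    print("\n".join(lines))

    combo = res.combo_map
    rows = ["modes,pct_area"]
    for subset, count in sorted(combo.combo_counts().items(),
                                key=lambda kv: -kv[1]):
        label = "+".join(sorted(subset)) if subset else "none"
        rows.append(f"{label},{100 * count / n:.2f}")
    (ROOT / "results" / "03_mode_combinations.csv").write_text(
        "\n".join(rows) + "\n")
    print("\n".join(rows))

    # quicklook map (scratch only)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(res.zones["all_modes"].zone, cmap="viridis_r")
        fig.colorbar(im, ax=ax, label="travel-time zone (all modes)")
        ax.set_title("30-minute travel-time zones, all-modes scenario")
        figdir = ROOT / "scratch" / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        fig.savefig(figdir / "03_all_modes_zones.png", dpi=120)
    except Exception as exc:  # plotting is a convenience, never load-bearing
        print(f"figure skipped: {exc}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
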