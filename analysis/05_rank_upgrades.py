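"""Rank non-EmONC delivery sites for upgrade to EmONC capability.

Greedy coverage maximization: each step upgrades the candidate whose 2-hour
catchment (motorcycle scenario) would newly cover the most births, i.e.
facilities sitting in high-birth-density areas with currently poor access.

Writes results/05_upgrade_ranking.csv (top picks with coverage gains).
"""

import sys
from pathlib import Path

import accesscape as ac
from accesscape.coverage import rank_upgrade_candidates
from accesscape.scenarios import default_speed_table

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0, k: int = 5) -> None:
    region = ac.generate_region(ac.LandscapeParams(seed=seed))
    combined = region.combined_landcover()
    candidates = [f for f in region.facilities if not f.is_emonc]
    picks = rank_upgrade_candidates(
        candidates, region.emonc_facilities, combined, region.dem,
        default_speed_table("motorcycle"), region.births, k=k, greedy=True,
    )
    lines = ["rank,facility_id,coverage_gain_births"]
    for i, (fac, gain) in enumerate(picks, 1):
        lines.append(f"{i},{fac.id},{gain:.0f}")
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "05_upgrade_ranking.csv").write_text(
        "\n".join(lines) + "\n")
    print("\n".join(lines))
    total = sum(g for _, g in picks)
    print(f"top-{k} upgrades would newly cover ~{total:.0f} births "
          f"({100 * total / region.births.total:.1f}% of the region)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
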