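"""Zonal birth statistics, access proportions and upgrade ranking."""

import numpy as np
import pytest
from shapely.geometry import box

from accesscape.catchments import Zone, ZoneRaster, classify_zones
from accesscape.cost import TravelTimeSurface, accumulate_travel_time
from accesscape.coverage import (
    AdminUnits,
    BirthRaster,
    DemographicParams,
    estimate_total_births,
    poor_access_by_unit,
    proportion_per_zone,
    rank_upgrade_candidates,
    zonal_birth_counts,
)
from accesscape.grid import ClassRaster, Dem, Facility, GridSpec, LandClass
from accesscape.scenarios import default_speed_table


def _zone_raster(zz, cell=30.0):
    zz = np.asarray(zz, dtype=np.int8)
    g = GridSpec(*zz.shape, cell, 0.0, zz.shape[0] * cell)
    return ZoneRaster(g, zz)


class TestZonalCounts:
    def test_uniform_births_split_proportionally(self):
        zz = np.zeros((10, 10), dtype=np.int8)
        zz[5:, :] = int(Zone.OVER_120)
        zones = _zone_raster(zz)
        births = BirthRaster(zones.grid, np.ones((10, 10)))
        counts = zonal_birth_counts(zones, births)
        assert counts[Zone.Z0_30] == 50.0
        assert counts[Zone.OVER_120] == 50.0

    def test_zero_births_all_zero(self):
        zones = _zone_raster(np.zeros((5, 5)))
        births = BirthRaster(zones.grid, np.zeros((5, 5)))
        assert all(v == 0 for v in zonal_birth_counts(zones, births).values())

    @pytest.mark.parametrize("seed", range(4))
    def test_cross_resolution_matches_bruteforce(self, seed):
        """Center-assignment of coarser birth cells onto a finer zone grid
        agrees with an explicit per-cell loop, and conserves the total."""
        rng = np.random.default_rng(seed)
        zones = _zone_raster(rng.integers(0, 5, (60, 60)))
        bg = GridSpec(18, 18, 100.0, 0.0, 1800.0)  # coarser, same footprint
        births = BirthRaster(bg, rng.integers(0, 20, (18, 18)).astype(float))
        counts = zonal_birth_counts(zones, births)

        expect = {z: 0.0 for z in Zone}
        for r in range(18):
            for c in range(18):
                x, y = bg.cell_center(r, c)
                zr, zc = zones.grid.world_to_cell(x, y)
                if 0 <= zr < 60 and 0 <= zc < 60:
                    z = Zone(zones.zone[zr, zc])
                else:
                    z = Zone.OVER_120
                expect[z] += births.births[r, c]
        for z in Zone:
            assert counts[z] == expect[z]
        assert sum(counts.values()) == births.births.sum()

    def test_birth_cells_outside_grid_go_to_poor_band(self):
        zones = _zone_raster(np.zeros((5, 5)))
        bg = GridSpec(5, 5, 30.0, 0.0, 180.0)  # top row off the zone grid
        births = BirthRaster(bg, np.ones((5, 5)))
        counts = zonal_birth_counts(zones, births)
        assert counts[Zone.OVER_120] == 5.0  # one off-grid row
        assert sum(counts.values()) == 25.0


class TestProportions:
    def test_simple_shares(self):
        p = proportion_per_zone({Zone.Z0_30: 10.0, Zone.OVER_120: 90.0})
        assert p[Zone.Z0_30] == pytest.approx(0.10)
        assert p[Zone.OVER_120] == pytest.approx(0.90)

    def test_single_zone_gets_one(self):
        p = proportion_per_zone({Zone.Z31_60: 42.0})
        assert p[Zone.Z31_60] == 1.0

    def test_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(0)
        zones = _zone_raster(rng.integers(0, 5, (20, 20)))
        b = rng.random((20, 20)) * 5
        p1 = proportion_per_zone(
            zonal_birth_counts(zones, BirthRaster(zones.grid, b)))
        p2 = proportion_per_zone(
            zonal_birth_counts(zones, BirthRaster(zones.grid, 7.3 * b)))
        for z in Zone:
            assert p1[z] == pytest.approx(p2[z], rel=1e-12)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            proportion_per_zone({Zone.Z0_30: 0.0})


class TestPerUnit:
    def _setup(self):
        g = GridSpec(10, 10, 30.0, 0.0, 300.0)
        minutes = np.zeros((10, 10))
        minutes[:, 5:] = 500.0  # east half poor
        surf = TravelTimeSurface(g, minutes)
        births = BirthRaster(g, np.ones((10, 10)))
        west = box(0, 0, 150, 300)
        east = box(150, 0, 300, 300)
        return surf, births, west, east

    def test_hand_computed_fractions(self):
        surf, births, west, east = self._setup()
        units = AdminUnits(["west", "east"], [west, east])
        out = poor_access_by_unit(surf, births, units)
        assert out["west"] == pytest.approx(0.0)
        assert out["east"] == pytest.approx(1.0)

    def test_mixed_council(self):
        surf, births, _, _ = self._setup()
        units = AdminUnits(["mid"], [box(60, 0, 240, 300)])  # 3 good, 3 poor cols
        out = poor_access_by_unit(surf, births, units)
        assert out["mid"] == pytest.approx(0.5)

    def test_zero_birth_council_reported_missing(self):
        surf, _, west, east = self._setup()
        births = BirthRaster(surf.grid, np.zeros((10, 10)))
        out = poor_access_by_unit(surf, births,
                                  AdminUnits(["west"], [west]))
        assert out["west"] is None


class TestTotalBirths:
    def test_product_formula(self):
        demo = DemographicParams(women_pop=470_000, growth_coeff=1.0,
                                 fertility_rate=0.21)
        assert estimate_total_births(0.0, demo) == 0.0
        assert estimate_total_births(1.0, demo) == pytest.approx(
            470_000 * 0.21)
        assert estimate_total_births(0.5, demo) == pytest.approx(
            470_000 * 0.21 * 0.5)

    def test_invalid_proportion(self):
        demo = DemographicParams(1000.0)
        with pytest.raises(ValueError):
            estimate_total_births(1.5, demo)


class TestUpgradeRanking:
    def _planted(self):
        """A wetland band isolates an eastern birth cluster from the only
        existing facility in the west; the candidate sits in the cluster."""
        n = 40
        g = GridSpec(n, n, 30.0, 0.0, n * 30.0)
        vals = np.full((n, n), int(LandClass.FORESTLAND), dtype=np.int16)
        vals[:, 20:22] = int(LandClass.WETLAND)
        lc = ClassRaster(g, vals)
        dem = Dem(g, np.zeros((n, n)))
        births = np.zeros((n, n))
        births[18:22, 30:34] = 25.0  # cluster of 400 births, east of the band
        births[5, 5] = 50.0
        b = BirthRaster(g, births)
        existing = [Facility("west", *g.cell_center(5, 5), "CEmONC")]
        good = Facility("east", *g.cell_center(20, 31), "non_EmONC")
        poor = Facility("near_west", *g.cell_center(6, 6), "non_EmONC")
        return lc, dem, b, existing, good, poor

    def test_planted_cluster_recovered(self):
        lc, dem, b, existing, good, poor = self._planted()
        t = default_speed_table("walking")
        ranked = rank_upgrade_candidates([poor, good], existing, lc, dem, t, b)
        assert ranked[0][0].id == "east"
        assert ranked[0][1] == pytest.approx(400.0, rel=0.01)
        assert all(g >= 0 for _, g in ranked)

    def test_contained_candidate_gains_nothing(self):
        lc, dem, b, existing, good, poor = self._planted()
        t = default_speed_table("walking")
        ranked = rank_upgrade_candidates([poor], existing, lc, dem, t, b)
        assert ranked[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_greedy_gains_non_increasing(self):
        lc, dem, b, existing, good, poor = self._planted()
        t = default_speed_table("walking")
        picks = rank_upgrade_candidates([poor, good], existing, lc, dem, t, b,
                                        k=2, greedy=True)
        gains = [g for _, g in picks]
        assert gains == sorted(gains, reverse=True)
        assert all(g >= -1e-9 for g in gains)

    def test_overlapping_candidates_raise(self):
        lc, dem, b, existing, good, _ = self._planted()
        t = default_speed_table("walking")
        with pytest.raises(ValueError, match="overlap"):
            rank_upgrade_candidates(existing, existing, lc, dem, t, b)

    def test_no_candidates_empty(self):
        lc, dem, b, existing, *_ = self._planted()
        t = default_speed_table("walking")
        assert rank_upgrade_candidates([], existing, lc, dem, t, b) == []
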