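"""Least-cost travel-time accumulation and its independent oracle."""

import math

import numpy as np
import pytest

from accesscape.cost import (
    EngineConfig,
    accumulate_travel_time,
    edge_time,
    oracle_travel_time,
    passable_mask,
)
from accesscape.grid import ClassRaster, Dem, GridSpec, LandClass
from accesscape.scenarios import SCENARIO_IDS, ToblerParams, default_speed_table

from conftest import make_uniform, random_mosaic


def _pick_sources(lc, table, rng, k=3):
    cells = np.argwhere(passable_mask(lc, table))
    idx = rng.choice(len(cells), size=min(k, len(cells)), replace=False)
    return [tuple(map(int, cells[i])) for i in idx]


class TestEdgeTime:
    def test_boat_step_hand_value(self):
        lc, dem = make_uniform(4, LandClass.BOAT_ROUTE)
        t = default_speed_table("walking")
        # 30 m at 15 km/h = 0.12 min
        assert edge_time(lc, dem, t, (1, 1), (1, 2)) == pytest.approx(0.12)

    def test_mixed_classes_harmonic_halves(self):
        lc, dem = make_uniform(4, LandClass.GRASSLAND)
        lc.values[1, 2] = int(LandClass.SETTLEMENT)
        t = default_speed_table("walking")
        expect = 15.0 * (1 / 1.7 + 1 / 2.5) * (60 / 1000)
        assert edge_time(lc, dem, t, (1, 1), (1, 2)) == pytest.approx(expect)

    def test_step_into_wetland_unreachable(self):
        lc, dem = make_uniform(4, LandClass.GRASSLAND)
        lc.values[1, 2] = int(LandClass.WETLAND)
        t = default_speed_table("walking")
        assert math.isinf(edge_time(lc, dem, t, (1, 1), (1, 2)))

    def test_walking_asymmetric_on_slope_vehicles_symmetric(self):
        lc, dem = make_uniform(4, LandClass.GRASSLAND)
        dem.elevation[:] = np.arange(4)[None, :] * 6.0  # constant east upslope
        w = default_speed_table("walking")
        up = edge_time(lc, dem, w, (1, 1), (1, 2))
        down = edge_time(lc, dem, w, (1, 2), (1, 1))
        assert up > down  # uphill slower than downhill
        cyc = default_speed_table("cycling")  # grassland is bicycle: isotropic
        assert edge_time(lc, dem, cyc, (1, 1), (1, 2)) == pytest.approx(
            edge_time(lc, dem, cyc, (1, 2), (1, 1))
        )

    def test_diagonal_squeeze_between_barriers_forbidden(self):
        lc, dem = make_uniform(4, LandClass.GRASSLAND)
        lc.values[1, 2] = int(LandClass.WETLAND)
        lc.values[2, 1] = int(LandClass.WETLAND)
        t = default_speed_table("walking")
        assert math.isinf(edge_time(lc, dem, t, (1, 1), (2, 2)))
        lc.values[2, 1] = int(LandClass.GRASSLAND)  # one side open again
        assert math.isfinite(edge_time(lc, dem, t, (1, 1), (2, 2)))

    def test_non_adjacent_raises(self):
        lc, dem = make_uniform(4)
        t = default_speed_table("walking")
        with pytest.raises(ValueError, match="adjacent"):
            edge_time(lc, dem, t, (0, 0), (0, 2))


class TestAccumulate:
    def test_single_step_equals_edge_time(self):
        lc, dem = make_uniform(5)
        t = default_speed_table("walking")
        s = accumulate_travel_time(lc, dem, t, [(2, 2)])
        assert s.minutes[2, 2] == 0.0
        assert s.minutes[2, 3] == pytest.approx(
            edge_time(lc, dem, t, (2, 3), (2, 2))
        )

    def test_rook_line_closed_form(self):
        lc, dem = make_uniform(8)
        t = default_speed_table("walking")
        s = accumulate_travel_time(lc, dem, t, [(0, 0)])
        step = edge_time(lc, dem, t, (0, 1), (0, 0))
        for k in range(1, 8):
            assert s.minutes[0, k] == pytest.approx(k * step, rel=1e-12)

    def test_multi_source_is_cellwise_min(self):
        lc, dem, rng = random_mosaic(11, n=20)
        t = default_speed_table("motorcycle")
        a, b = _pick_sources(lc, t, rng, 2)
        s_ab = accumulate_travel_time(lc, dem, t, [a, b])
        s_a = accumulate_travel_time(lc, dem, t, [a])
        s_b = accumulate_travel_time(lc, dem, t, [b])
        assert np.allclose(
            s_ab.minutes, np.minimum(s_a.minutes, s_b.minutes), equal_nan=False
        )

    @pytest.mark.parametrize("scenario", SCENARIO_IDS)
    def test_matches_oracle_on_random_mosaic(self, scenario):
        lc, dem, rng = random_mosaic(5, n=25)
        t = default_speed_table(scenario)
        src = _pick_sources(lc, t, rng)
        fast = accumulate_travel_time(lc, dem, t, src)
        ref = oracle_travel_time(lc, dem, t, src)
        assert np.array_equal(fast.unreachable, ref.unreachable)
        m = ~ref.unreachable
        assert np.allclose(fast.minutes[m], ref.minutes[m], rtol=1e-9, atol=0)

    def test_matches_oracle_16_connectivity(self):
        lc, dem, rng = random_mosaic(21, n=18)
        t = default_speed_table("walking")
        src = _pick_sources(lc, t, rng, 2)
        cfg = EngineConfig(connectivity=16)
        fast = accumulate_travel_time(lc, dem, t, src, cfg)
        ref = oracle_travel_time(lc, dem, t, src, cfg)
        m = ~ref.unreachable
        assert np.array_equal(fast.unreachable, ref.unreachable)
        assert np.allclose(fast.minutes[m], ref.minutes[m], rtol=1e-9, atol=0)

    def test_source_monotonicity(self):
        lc, dem, rng = random_mosaic(31, n=20)
        t = default_speed_table("car")
        src = _pick_sources(lc, t, rng, 3)
        s2 = accumulate_travel_time(lc, dem, t, src[:2])
        s3 = accumulate_travel_time(lc, dem, t, src)
        assert np.all(s3.minutes <= s2.minutes + 1e-12)

    def test_scenario_speed_dominance_cellwise(self):
        lc, dem, rng = random_mosaic(41, n=25)
        tw = default_speed_table("walking")
        src = _pick_sources(lc, tw, rng, 2)
        surf = {
            sid: accumulate_travel_time(lc, dem, default_speed_table(sid), src)
            for sid in SCENARIO_IDS
        }
        assert np.all(surf["car"].minutes <= surf["walking"].minutes + 1e-9)
        assert np.all(
            surf["motorcycle"].minutes <= surf["cycling"].minutes + 1e-9
        )

    def test_metric_bound_on_uniform_grid(self):
        """8-connectivity distance exceeds the Euclidean metric by at most
        1/cos(pi/8) - 1 on a uniform landscape."""
        n = 21
        lc, dem = make_uniform(n, LandClass.SETTLEMENT)
        t = default_speed_table("walking")
        src = (n // 2, n // 2)
        s = accumulate_travel_time(lc, dem, t, [src])
        eps = 1 / math.cos(math.pi / 8) - 1
        v_m_per_min = 2.5 * 1000 / 60
        for r in range(n):
            for c in range(n):
                d = math.hypot(r - src[0], c - src[1]) * 30.0
                straight = d / v_m_per_min
                assert s.minutes[r, c] <= straight * (1 + eps) + 1e-9
                assert s.minutes[r, c] >= straight - 1e-9

    def test_barriers_stay_unreachable(self):
        lc, dem, _ = random_mosaic(51, n=20)
        t = default_speed_table("walking")
        cells = np.argwhere(passable_mask(lc, t))
        s = accumulate_travel_time(lc, dem, t, [tuple(map(int, cells[0]))])
        barrier = ~passable_mask(lc, t)
        assert np.all(s.unreachable[barrier])

    def test_no_sources_raises(self):
        lc, dem = make_uniform(5)
        t = default_speed_table("walking")
        with pytest.raises(ValueError):
            accumulate_travel_time(lc, dem, t, [])

    def test_all_sources_on_barriers_raises(self):
        lc, dem = make_uniform(5)
        lc.values[2, 2] = int(LandClass.WETLAND)
        t = default_speed_table("walking")
        with pytest.raises(ValueError, match="impassable"):
            accumulate_travel_time(lc, dem, t, [(2, 2)])

    def test_disabling_normalization_rescales_uniform_terrain(self):
        """Without flat-normalization all walking times scale by one constant."""
        lc, dem = make_uniform(10, LandClass.GRASSLAND)
        t = default_speed_table("walking")
        p0 = ToblerParams(normalize_to_flat=True)
        p1 = ToblerParams(normalize_to_flat=False)
        s0 = accumulate_travel_time(lc, dem, t, [(0, 0)], params=p0)
        s1 = accumulate_travel_time(lc, dem, t, [(0, 0)], params=p1)
        k = math.exp(p0.steepness * p0.offset)
        m = s0.minutes > 0
        assert np.allclose(s1.minutes[m] / s0.minutes[m], k, rtol=1e-12)


class TestOracle:
    def test_direction_asymmetry_on_constant_slope(self):
        """Walking downhill to a facility is faster than walking uphill to it."""
        n = 6
        lc, dem = make_uniform(n, LandClass.GRASSLAND)
        dem.elevation[:] = np.arange(n)[None, :] * 9.0  # rises to the east
        t = default_speed_table("walking")
        west = oracle_travel_time(lc, dem, t, [(3, 0)])  # travel downhill
        east = oracle_travel_time(lc, dem, t, [(3, n - 1)])  # travel uphill
        assert west.minutes[3, n - 1] > east.minutes[3, 0] * 0  # both finite
        # time from the east edge to the west facility (downhill) is less
        # than from the west edge to the east facility (uphill)
        assert west.minutes[3, n - 1] < east.minutes[3, 0]
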