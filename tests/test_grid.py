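"""Raster data model: rasterization, burn order, facility snapping, slope."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from accesscape.grid import (
    ClassRaster,
    Dem,
    Facility,
    Feature,
    GridSpec,
    LandClass,
    NODATA_CODE,
    VectorLayer,
    build_combined_landcover,
    directional_slope,
    neighbor_offsets,
    rasterize_layer,
    snap_facilities,
)


def _grid(n, cell=30.0):
    return GridSpec(n, n, cell, 0.0, n * cell)


class TestRasterize:
    def test_horizontal_line_burns_middle_row(self):
        g = _grid(5)
        y = g.cell_center(2, 0)[1]
        layer = VectorLayer(
            "polyline", [Feature(LineString([(0, y), (150, y)]),
                                 LandClass.MAJOR_ROAD)]
        )
        out = rasterize_layer(layer, g, LandClass.MAJOR_ROAD)
        assert (out.values[2, :] == int(LandClass.MAJOR_ROAD)).all()
        assert (out.values[[0, 1, 3, 4], :] == NODATA_CODE).all()

    def test_empty_layer_all_nodata(self):
        g = _grid(5)
        out = rasterize_layer(VectorLayer("polyline", []), g,
                              LandClass.MAJOR_ROAD)
        assert (out.values == NODATA_CODE).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_distance_oracle(self, seed):
        """Center-within-half-cell burning equals an exhaustive per-cell
        point-to-segment distance check."""
        rng = np.random.default_rng(seed)
        n = 12
        g = _grid(n)
        pts = rng.uniform(0, n * 30.0, size=(3, 2))
        line = LineString(pts)
        layer = VectorLayer("polyline",
                            [Feature(line, LandClass.SECONDARY_ROAD)])
        out = rasterize_layer(layer, g, LandClass.SECONDARY_ROAD)
        for r in range(n):
            for c in range(n):
                d = line.distance(Point(g.cell_center(r, c)))
                expect = d <= 15.0
                got = out.values[r, c] == int(LandClass.SECONDARY_ROAD)
                assert got == expect, (r, c, d)

    def test_diagonal_corner_to_corner(self):
        g = _grid(4)
        line = LineString([(0, g.origin_y), (120.0, g.origin_y - 120.0)])
        out = rasterize_layer(
            VectorLayer("polyline", [Feature(line, LandClass.MAJOR_ROAD)]), g,
            LandClass.MAJOR_ROAD,
        )
        for r in range(4):
            for c in range(4):
                d = line.distance(Point(g.cell_center(r, c)))
                assert (out.values[r, c] != NODATA_CODE) == (d <= 15.0)


class TestCombined:
    def _base(self, n=7, cls=LandClass.GRASSLAND):
        g = _grid(n)
        return ClassRaster(g, np.full((n, n), int(cls), dtype=np.int16))

    def test_no_layers_identity(self):
        base = self._base()
        out = build_combined_landcover(base)
        assert np.array_equal(out.values, base.values)

    def test_road_over_river_is_bridge(self):
        """Burn order base < rivers < roads: the crossing cell stays a road."""
        base = self._base()
        g = base.grid
        y = g.cell_center(3, 0)[1]
        x = g.cell_center(0, 3)[0]
        rivers = VectorLayer(
            "polyline",
            [Feature(LineString([(0, y), (g.width_m, y)]),
                     LandClass.RIVER_BARRIER)],
        )
        roads = VectorLayer(
            "polyline",
            [Feature(LineString([(x, g.origin_y), (x, 0)]),
                     LandClass.SECONDARY_ROAD)],
        )
        out = build_combined_landcover(base, rivers, roads)
        assert out.values[3, 3] == int(LandClass.SECONDARY_ROAD)
        assert out.values[3, 0] == int(LandClass.RIVER_BARRIER)
        assert out.values[0, 3] == int(LandClass.SECONDARY_ROAD)

    def test_boat_route_burn(self):
        base = self._base(cls=LandClass.CROPLAND)
        g = base.grid
        y = g.cell_center(5, 0)[1]
        boats = VectorLayer(
            "polyline",
            [Feature(LineString([(0, y), (g.width_m, y)]),
                     LandClass.BOAT_ROUTE)],
        )
        out = build_combined_landcover(base, boat_routes=boats)
        assert (out.values[5, :] == int(LandClass.BOAT_ROUTE)).all()

    def test_major_road_over_settlement_recoded_residential(self):
        base = self._base()
        base.values[:, 2] = int(LandClass.SETTLEMENT)
        g = base.grid
        y = g.cell_center(1, 0)[1]
        roads = VectorLayer(
            "polyline",
            [Feature(LineString([(0, y), (g.width_m, y)]),
                     LandClass.MAJOR_ROAD)],
        )
        out = build_combined_landcover(base, roads=roads)
        assert out.values[1, 2] == int(LandClass.MAJOR_ROAD_RESIDENTIAL)
        assert out.values[1, 1] == int(LandClass.MAJOR_ROAD)

    @pytest.mark.parametrize("seed", range(3))
    def test_roads_never_become_river_barrier(self, seed):
        """Burn-order property: road-covered cells never carry the river code."""
        rng = np.random.default_rng(seed)
        base = self._base(12)
        g = base.grid
        mk = lambda: LineString(rng.uniform(0, g.width_m, (2, 2)))
        rivers = VectorLayer(
            "polyline", [Feature(mk(), LandClass.RIVER_BARRIER) for _ in range(4)]
        )
        road_line = mk()
        roads = VectorLayer("polyline",
                            [Feature(road_line, LandClass.LOCAL_ROAD_ALL)])
        out = build_combined_landcover(base, rivers, roads)
        mask = rasterize_layer(roads, g, LandClass.LOCAL_ROAD_ALL)
        covered = mask.values != NODATA_CODE
        assert not np.any(out.values[covered] == int(LandClass.RIVER_BARRIER))


class TestSnap:
    def _combined(self):
        g = _grid(6)
        vals = np.full((6, 6), int(LandClass.GRASSLAND), dtype=np.int16)
        vals[2, 2] = int(LandClass.WETLAND)
        vals[2, 3] = int(LandClass.SETTLEMENT)
        return ClassRaster(g, vals)

    def test_center_of_passable_cell(self):
        c = self._combined()
        x, y = c.grid.cell_center(4, 1)
        res = snap_facilities([Facility("f1", x, y, "CEmONC")], c)
        assert res.sources == [(4, 1)]

    def test_barrier_cell_snaps_to_nearest_passable(self):
        c = self._combined()
        x, y = c.grid.cell_center(2, 2)
        res = snap_facilities([Facility("f1", x, y, "CEmONC")], c)
        assert res.sources[0] != (2, 2)
        assert res.snapped["f1"][0] == (2, 2)
        # adjacent settlement cell is among the nearest passable cells
        r, cc = res.sources[0]
        assert math.hypot(r - 2, cc - 2) == 1.0

    def test_two_facilities_one_cell_dedup(self):
        c = self._combined()
        x, y = c.grid.cell_center(1, 1)
        res = snap_facilities(
            [Facility("a", x, y, "CEmONC"), Facility("b", x, y, "non_EmONC")], c
        )
        assert res.sources == [(1, 1)]
        assert res.ids_by_cell[(1, 1)] == ["a", "b"]

    def test_unsnappable_facility_raises_with_id(self):
        g = _grid(5)
        vals = np.full((5, 5), int(LandClass.WETLAND), dtype=np.int16)
        c = ClassRaster(g, vals)
        x, y = g.cell_center(2, 2)
        with pytest.raises(ValueError, match="lonely"):
            snap_facilities([Facility("lonely", x, y, "CEmONC")], c,
                            snap_radius_cells=2)

    def test_outside_grid_raises(self):
        c = self._combined()
        with pytest.raises(ValueError, match="outside"):
            snap_facilities([Facility("f", -10.0, -10.0, "CEmONC")], c)


class TestSlope:
    def test_flat_dem_zero(self):
        g = _grid(4)
        dem = Dem(g, np.full((4, 4), 1000.0))
        for dr, dc in neighbor_offsets(8):
            assert directional_slope(dem, (2, 2), (2 + dr, 2 + dc)) == 0.0

    def test_rook_step_rise_over_run(self):
        g = _grid(4)
        e = np.full((4, 4), 100.0)
        e[2, 3] = 103.0
        dem = Dem(g, e)
        assert directional_slope(dem, (2, 2), (2, 3)) == pytest.approx(0.1)

    def test_diagonal_step(self):
        g = _grid(4)
        e = np.full((4, 4), 100.0)
        e[3, 3] = 103.0
        dem = Dem(g, e)
        expect = 3.0 / (30.0 * math.sqrt(2))
        assert directional_slope(dem, (2, 2), (3, 3)) == pytest.approx(expect)
        assert expect == pytest.approx(0.0707, abs=1e-4)

    @pytest.mark.parametrize("seed", range(3))
    def test_antisymmetry_on_random_dem(self, seed):
        rng = np.random.default_rng(seed)
        g = _grid(6)
        dem = Dem(g, rng.uniform(800, 2400, (6, 6)))
        for r in range(6):
            for c in range(6):
                for dr, dc in neighbor_offsets(8):
                    rr, cc = r + dr, c + dc
                    if not g.contains_cell(rr, cc):
                        continue
                    assert directional_slope(dem, (r, c), (rr, cc)) == -(
                        directional_slope(dem, (rr, cc), (r, c))
                    )

    def test_non_adjacent_raises(self):
        g = _grid(5)
        dem = Dem(g, np.zeros((5, 5)))
        with pytest.raises(ValueError, match="adjacent"):
            directional_slope(dem, (0, 0), (3, 3))
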