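"""Shared fixtures: small uniform landscapes and a compact synthetic region."""

from __future__ import annotations

import numpy as np
import pytest

import accesscape as ac
from accesscape.grid import GridSpec, ClassRaster, Dem, LandClass
from accesscape.synthetic import LandscapeParams


def make_uniform(n: int = 10, cls: LandClass = LandClass.GRASSLAND,
                 cell: float = 30.0, elev: float = 0.0):
    """Uniform single-class landscape with a flat DEM."""
    g = GridSpec(n, n, cell, 0.0, n * cell)
    lc = ClassRaster(g, np.full((n, n), int(cls), dtype=np.int16))
    dem = Dem(g, np.full((n, n), elev))
    return lc, dem


def random_mosaic(seed: int, n: int = 40, cell: float = 30.0):
    """Random class mosaic (with barriers) and a random rough DEM."""
    rng = np.random.default_rng(seed)
    codes = np.array([int(c) for c in LandClass])
    p = np.ones(len(codes))
    p[codes == int(LandClass.WETLAND)] = 2.0  # more barriers
    p /= p.sum()
    vals = rng.choice(codes, size=(n, n), p=p)
    g = GridSpec(n, n, cell, 0.0, n * cell)
    lc = ClassRaster(g, vals)
    dem = Dem(g, rng.uniform(800.0, 2400.0, (n, n)))
    return lc, dem, rng


def small_params(seed: int = 0) -> LandscapeParams:
    """A compact synthetic region for fast end-to-end tests."""
    return LandscapeParams(
        grid=GridSpec(100, 100, cell_size=100.0, origin_x=0.0,
                      origin_y=10_000.0, crs_label="synthetic-utm-like-meters"),
        n_towns=6,
        n_facilities_emonc=3,
        n_facilities_total=12,
        n_councils=4,
        river_count=2,
        births_total=5000,
        births_cell_size=250.0,  # divides the 10 km extent evenly
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_region():
    return ac.generate_region(small_params(0))


@pytest.fixture(scope="session")
def default_region():
    """The full-scale default synthetic region (seed 0)."""
    return ac.generate_region(ac.kigoma_like_defaults())


@pytest.fixture(scope="session")
def default_analysis(default_region):
    from accesscape.pipeline import run_analysis

    r = default_region
    return run_analysis(r.combined_landcover(), r.dem, r.facilities,
                        r.births, r.councils)
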