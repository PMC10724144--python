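"""Shared synthetic worlds and fitted pipelines (session-scoped: the heavier
fixtures run the real two-stage pipeline once and are reused across files)."""

import numpy as np
import pytest

from gaplesspm import aod_gapfill, pm25_retrieval, synthworld
from gaplesspm.stet_model import StetConfig


@pytest.fixture(scope="session")
def tiny_world():
    """Smallest full-year world: cheap enough for per-test pipelines."""
    cfg = synthworld.WorldConfig(
        n_lat=8, n_lon=12, n_stations=8, n_countries=4, seed=5
    )
    return synthworld.generate_world(cfg)


@pytest.fixture(scope="session")
def small_world():
    """Default-structure world at reduced grid size."""
    cfg = synthworld.WorldConfig(
        n_lat=16, n_lon=24, n_stations=20, n_countries=6, seed=3
    )
    return synthworld.generate_world(cfg)


@pytest.fixture(scope="session")
def small_gapless(small_world):
    """Gap-filled AOD on the small world plus the merge/coverage report."""
    return aod_gapfill.run_gapfill(small_world)


@pytest.fixture(scope="session")
def small_retrieval(small_world, small_gapless):
    """(pm_field, model, training_table) of the small-world retrieval."""
    gapless, _ = small_gapless
    return pm25_retrieval.run_retrieval(small_world, gapless)


@pytest.fixture(scope="session")
def cv_config():
    """Lighter forest for the cross-validation batteries (runtime choice)."""
    return StetConfig(n_trees=60, min_leaf=2, seed=0)


@pytest.fixture(scope="session")
def cv_world():
    """World for the CV skill and ordering checks."""
    cfg = synthworld.WorldConfig(
        n_lat=20, n_lon=30, n_stations=50, n_countries=8, seed=11
    )
    return synthworld.generate_world(cfg)


@pytest.fixture(scope="session")
def cv_table(cv_world):
    """Stage-2 training table of the cv_world pipeline, with region labels."""
    gapless, _ = aod_gapfill.run_gapfill(cv_world)
    _, _, table = pm25_retrieval.run_retrieval(cv_world, gapless)
    labels = cv_world.regions[["cell_i", "cell_j", "state", "continent"]]
    return table.merge(labels, on=["cell_i", "cell_j"], how="left")


@pytest.fixture(scope="session")
def noiseless_cv_table():
    """Training table of a noiseless world (pm an exact function of truth)."""
    cfg = synthworld.WorldConfig(
        n_lat=20, n_lon=30, n_stations=50, n_countries=8, seed=11,
        noise_sd=0.0,
        outlier_rates={"negative": 0.0, "repeat": 0.0, "extreme": 0.0},
    )
    world = synthworld.generate_world(cfg)
    gapless, _ = aod_gapfill.run_gapfill(world)
    _, _, table = pm25_retrieval.run_retrieval(world, gapless)
    return table


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
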