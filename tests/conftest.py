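import numpy as np
import pytest

from betelmap.core_io import Affine, RasterGrid
from betelmap.pipeline import run_pipeline
from betelmap.synthetic_scene import SceneConfig, default_scene, simulate_scene

BENCH_SEED = 1


@pytest.fixture(scope="session")
def bench_result():
    """One full pipeline run on the default 256x256 scene, shared by the
    end-to-end assertions (forest mask quality, betel accuracy, invariants)."""
    return run_pipeline(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def small_scene():
    """A 96x96 scene for cheaper stage-level tests."""
    cfg, rad = default_scene()
    cfg = SceneConfig(shape=(96, 96), seed=3)
    return simulate_scene(cfg, rad, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_grid(values, nodata=np.nan):
    return RasterGrid(np.asarray(values, dtype=float), Affine(), nodata=nodata)


@pytest.fixture
def grid_factory():
    return make_grid
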