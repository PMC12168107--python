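import numpy as np
import pytest

from bioregionet import pipeline
from bioregionet.grid import make_grid

SCENE_SEED = 1


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default scene (16,200-cell grid, 69
    species): regionalization (100 restarts), region models, and a +2 degC
    10-pseudo-GCM projection. Shared across tests to keep the suite fast."""
    import time

    t0 = time.time()
    scene = pipeline.build_scene(seed=SCENE_SEED)
    reg = pipeline.regionalize(scene, n_runs=100)
    models = pipeline.fit_models(scene, reg)
    proj = pipeline.project_warming(scene, models)
    return {
        "scene": scene,
        "reg": reg,
        "models": models,
        "proj": proj,
        "elapsed_s": time.time() - t0,
    }


@pytest.fixture(scope="session")
def small_scene():
    """Cheap scene for module-level tests: 80 x 45 cells, 45 species."""
    grid = make_grid(lon_min=-40, lon_max=40)
    return pipeline.build_scene(
        seed=11, grid=grid, n_south=20, n_subtrop=20, n_widespread=3, n_local=2
    )


@pytest.fixture(scope="session")
def small_reg(small_scene):
    return pipeline.regionalize(small_scene, n_runs=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
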