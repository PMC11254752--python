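import numpy as np
import pytest

import forestedge as fe
from forestedge.scenarios import stationary_world_config


@pytest.fixture(scope="session")
def small_world():
    """Modest default-dynamics landscape shared by the structural tests."""
    cfg = fe.SimulationConfig(grid_size=128, n_footprints=4000, seed=7)
    stack, aux, truth = fe.simulate_landscape(cfg)
    return cfg, stack, aux, truth


@pytest.fixture(scope="session")
def small_world_sample(small_world):
    cfg, stack, aux, truth = small_world
    fp = fe.simulate_footprints(stack, truth, cfg)
    clean, _ = fe.apply_quality_filters(fp, "other")
    strata = fe.derive_strata(stack, aux["fire_year"], aux["logging_polygons"])
    gs = fe.GridSpec(cell_size=cfg.grid_size * cfg.pixel_size)
    sample, report = fe.colocate_footprints(clean, strata, gs)
    return sample, report, strata


@pytest.fixture(scope="session")
def stationary_sample():
    """One stationary-world realisation with its ground truth."""
    from forestedge.experiments import stratified_sample_for

    cfg = stationary_world_config(seed=3)
    sample, truth, stack = stratified_sample_for(cfg)
    return sample, truth, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
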