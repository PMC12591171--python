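import numpy as np
import pytest

from socbench import synthetic_data as sd


@pytest.fixture(scope="session")
def obs_small():
    """Moderate two-fraction observation table shared across tests."""
    cfg = sd.default_config("maoc", seed=42)
    cfg.n_studies, cfg.sites_per_study = 24, 12
    comp = sd.default_config("poc", seed=42)
    ds, truth = sd.generate_observations(cfg, comp)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def landscape_small():
    """16x16 synthetic grid with its ground truth."""
    cfg = sd.default_config("maoc", seed=7)
    cfg.grid_shape = (16, 16)
    grid, truth = sd.generate_grid(cfg)
    return grid, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
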