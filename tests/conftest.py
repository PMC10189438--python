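import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import minibr as mb

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return mb.default_config("medium")


@pytest.fixture(scope="session")
def medium_field_small(default_cfg):
    """Medium-regime flow on a coarse grid, shared across test modules."""
    cfg = default_cfg
    return mb.solve_flow(cfg.vessel, cfg.fluid, cfg.impeller,
                         resolution=(32, 48))


@pytest.fixture(scope="session")
def small_run(default_cfg):
    """A reduced medium-regime suspension run (coarse grid, 60 particles,
    20 s) reused by suspension- and stress-level tests."""
    cfg = mb.default_config("medium", n_particles=60, seed=7, duration=20.0,
                            sample_every=50, grid=(32, 48))
    field = mb.solve_flow(cfg.vessel, cfg.fluid, cfg.impeller,
                          resolution=cfg.grid)
    trajs = mb.simulate(cfg, field)
    return cfg, field, trajs
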