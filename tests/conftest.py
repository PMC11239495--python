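import numpy as np
import pytest

import glucotrack as gt


@pytest.fixture(scope="session")
def session_bundle():
    """A default synthetic session shared by read-only tests."""
    cfg = gt.SimConfig(seed=7, n_cells=40)
    session, cell_time, cells, truth = gt.simulate_session(cfg)
    return cfg, session, cell_time, cells, truth


@pytest.fixture(scope="session")
def noiseless_glucose():
    """Noiseless default transient on the default grid, with its config."""
    cfg = gt.SimConfig(seed=0, n_cells=1)
    params = gt.GlucoseParams(noise_sd=0.0)
    t = np.arange(int(cfg.duration))
    rng = np.random.default_rng(0)
    g = gt.simulate_glucose(params, t, cfg.infusion_time, rng)
    return t, g, params, cfg.infusion_time
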