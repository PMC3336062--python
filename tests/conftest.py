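import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_study():
    """A small, fast synthetic study shared across tests (design seed 100)."""
    from hmfuse.synthetic import default_config, simulate_study

    cfg = default_config(seed=100, n_per_group=4)
    cfg.n_points = 512
    block_a, block_b, truth = simulate_study(cfg)
    return cfg, block_a, block_b, truth
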