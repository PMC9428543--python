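import numpy as np
import pandas as pd
import pytest

from reefiso.simulate import SimConfig, generate_sites, generate_fish, generate_baselines


@pytest.fixture(scope="session")
def paper_like():
    """One paper-like synthetic dataset at study dimensions."""
    cfg = SimConfig.preset("paper-like", seed=42)
    sites = generate_sites(cfg)
    tissue, otoliths = generate_fish(cfg, sites)
    baselines = generate_baselines(cfg, sites)
    return cfg, sites, tissue, otoliths, baselines


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
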