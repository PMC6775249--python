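import numpy as np
import pandas as pd
import pytest

from sncpipe import synthetic as syn


@pytest.fixture(scope="session")
def annotation() -> pd.DataFrame:
    """Small mixed tRNA/YRNA annotation on two chromosomes, both strands."""
    return syn.simulate_annotation(n_trna=12, n_yrna=4, seed=42)


@pytest.fixture
def base_cfg() -> syn.SimulationConfig:
    return syn.SimulationConfig(seed=7, n_features=300)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
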