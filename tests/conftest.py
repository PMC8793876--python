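import numpy as np
import pandas as pd
import pytest

from xylemcomp.compstats import TraitTable
from xylemcomp.synthgen import SynthConfig, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def yule_tree():
    """Deterministic 28-tip unit-depth Yule tree."""
    return simulate_tree(SynthConfig(n_species=28, seed=7))


@pytest.fixture
def tree_factory():
    def make(n_tips=10, seed=0):
        return simulate_tree(SynthConfig(n_species=n_tips, seed=seed))

    return make


@pytest.fixture
def trait_table_factory():
    def make(values: dict[str, np.ndarray], species=None):
        n = len(next(iter(values.values())))
        idx = species if species is not None else [f"sp{i + 1:02d}" for i in range(n)]
        return TraitTable(pd.DataFrame(values, index=idx))

    return make
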