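import numpy as np
import pytest

from foldcraft import EngineConfig, FoldingEngine
from foldcraft.fixtures import StructureGenConfig, random_structure


@pytest.fixture(scope="session")
def engine():
    """One shared Turner1999-configured folding engine (cached)."""
    return FoldingEngine(EngineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_structures(n, seed, min_len=10, max_len=60):
    """Varied random valid structures for property tests."""
    gen = np.random.default_rng(seed)
    cfgs = [
        StructureGenConfig(min_len=min_len, max_len=max_len, max_depth=3,
                           bulge_weight=0.4, internal_weight=0.4,
                           multiloop_weight=0.3),
        StructureGenConfig(min_len=min_len, max_len=max_len, max_depth=2),
    ]
    return [random_structure(cfgs[i % len(cfgs)], gen) for i in range(n)]
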