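import numpy as np
import pytest

from dupdiverge.simulate import SynthConfig, gen_duplicated_genome


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic genome shared across read-only tests."""
    cfg = SynthConfig(seed=11, n_pairs=8, n_quads=2)
    return cfg, gen_duplicated_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
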