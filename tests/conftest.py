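import numpy as np
import pytest

import clonotrace as ct


@pytest.fixture
def rng():
    return np.random.default_rng(20170913)


@pytest.fixture
def small_noiseless():
    """A tiny noiseless two-clone dataset for exact-recovery checks."""
    cfg = ct.noiseless(
        ct.SimulationConfig(
            seed=11, n_cells=24, n_snv=10, n_sv=8, background_reads=30
        )
    )
    return ct.simulate_dataset(cfg)


def random_reads(rng, n, length=80):
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]
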