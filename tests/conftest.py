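import numpy as np
import pytest

from freqtagsl import blocks, synth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_cohort():
    """One default fast-mode cohort shared by read-only tests."""
    return synth.simulate_cohort(master_seed=42, mode="fast")


@pytest.fixture(scope="session")
def block_table(fast_cohort):
    return blocks.finalize_block_table(fast_cohort.blocks)
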