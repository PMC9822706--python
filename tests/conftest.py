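import numpy as np
import pytest

import collocerp as c


@pytest.fixture(scope="session")
def item_table():
    """The packaged 26-item adjective-noun stimulus table."""
    return c.load_item_table()


@pytest.fixture(scope="session")
def scored_items(item_table):
    return c.score_and_classify(item_table)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_synth():
    """A quick 2-participant dataset with enough trials for stable averages."""
    cfg = c.SynthConfig(
        seed=424242, n_participants=2, n_critical_per_condition=12,
        lag_range_samples=100,
    )
    return c.generate_dataset(cfg)
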