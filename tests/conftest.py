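import numpy as np
import pytest

import crownclust as cc


@pytest.fixture(scope="session")
def default10_profiles():
    return cc.profile_pack("default10")


@pytest.fixture(scope="session")
def default10_dataset(default10_profiles):
    """The standard synthetic forest: 10 species x 10 trees, fixed seed."""
    return cc.generate_dataset(default10_profiles, 10, seed=1)


@pytest.fixture(scope="session")
def default10_features(default10_dataset):
    return cc.extract_all(default10_dataset)


@pytest.fixture(scope="session")
def sample_trees(default10_dataset):
    """A handful of individual trees spanning different crown shapes."""
    ids = default10_dataset.tree_ids
    picks = [ids[0], ids[15], ids[42], ids[77]]
    return [default10_dataset[t] for t in picks]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
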