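import numpy as np
import pytest

from connharm.synthetic import SyntheticSpec, generate_multisite_dataset
from connharm.training import TrainConfig, train_model


@pytest.fixture(scope="session")
def small_synthetic():
    """Two-site dataset at reduced scale with a known 10-feature class effect."""
    spec = SyntheticSpec(n_features=60, n_per_site_per_class=40, seed=3)
    return generate_multisite_dataset(spec)


@pytest.fixture(scope="session")
def trained_small(small_synthetic):
    """A SHRED-III model trained on 80% of the small dataset (shared: slow)."""
    ds = small_synthetic.dataset
    rng = np.random.default_rng(0)
    idx = rng.permutation(ds.n_subjects)
    k = int(0.8 * idx.size)
    train_idx, test_idx = np.sort(idx[:k]), np.sort(idx[k:])
    trained = train_model(ds.subset(train_idx), TrainConfig(epochs=15, seed=1),
                          "shred_iii")
    return small_synthetic, train_idx, test_idx, trained
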