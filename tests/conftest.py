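import numpy as np
import pytest

from attnmil import synthdata


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 3-class dataset with clear signal for functional tests."""
    cfg = synthdata.BagSimConfig(
        n_classes=3, bags_per_class=6, instances_per_bag=(30, 60),
        feature_dim=16, signal_prevalence=0.2, prototype_separation=6.0,
        noise_sd=0.5, seed=11,
    )
    bags, labels, flags = synthdata.generate_bag_dataset(cfg)
    return bags, labels, flags


@pytest.fixture
def rng():
    return np.random.default_rng(0)
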