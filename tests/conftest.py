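import numpy as np
import pytest

from radwise.io import FeatureTable
from radwise.synth import SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_table() -> FeatureTable:
    """4 samples × 3 features, labels [0, 0, 1, 1]."""
    return FeatureTable(
        values=np.array([[1.0, 2.0, 3.0],
                         [2.0, 1.0, 4.0],
                         [5.0, 2.5, 3.5],
                         [6.0, 1.5, 4.5]]),
        feature_names=["fA", "fB", "fC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def small_panel():
    """A small planted panel: 20 patients, 60 features, 4 informative."""
    spec = SyntheticSpec(seed=7, n_patients=20, n_features=60,
                         n_informative=4, n_proxies_per_informative=1)
    return generate_dataset(spec)


@pytest.fixture
def medium_panel():
    """30 patients × 150 features with the default effect size."""
    spec = SyntheticSpec(seed=3, n_patients=30, n_features=150,
                         n_informative=5, n_proxies_per_informative=2)
    return generate_dataset(spec)
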