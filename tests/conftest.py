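import numpy as np
import pytest

from mccit.data import LabeledDataset
from mccit.synthetic import gen_categorical_dataset, gen_ordinal_dataset


@pytest.fixture
def counts_532_dataset():
    """n=10 dataset with class counts (5, 3, 2) and irrelevant features."""
    rng = np.random.default_rng(42)
    y = np.repeat([0, 1, 2], [5, 3, 2])
    return LabeledDataset(rng.standard_normal((10, 3)), y, "nominal")


@pytest.fixture
def nominal_dataset():
    data, truth = gen_categorical_dataset(200, 6, 3, 2, effect_size=1.0, seed=11)
    return data, truth


@pytest.fixture
def ordinal_dataset():
    data, truth = gen_ordinal_dataset(200, 6, 4, 2, effect_size=1.0, seed=12)
    return data, truth
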