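import warnings

import numpy as np
import pytest

from nmrtune import (
    SyntheticSpec,
    generate_tabular,
    planted_recovery_fixture,
    stratified_kfold,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_planted():
    """300-sample, 8-feature dataset with 3 strongly relevant features."""
    dataset, mask = planted_recovery_fixture(p=8, n_relevant=3, n=300, seed=0)
    return dataset, mask


@pytest.fixture(scope="session")
def small_plan(small_planted):
    dataset, _ = small_planted
    return stratified_kfold(dataset.y, 5, seed=0)


@pytest.fixture(scope="session")
def thyroid_like():
    """Desk-scale draw from the default thyroid-schema generator."""
    return generate_tabular(SyntheticSpec(n=400, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
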