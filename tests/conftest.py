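import warnings

import numpy as np
import pytest

from milfc.estimator import TrainConfig, init_params, train_fc_estimator
from milfc.synthetic import simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """60 slides with modest bags; enough signal to train quickly."""
    return simulate_cohort(60, n_patches_range=(80, 160), seed=42)


@pytest.fixture(scope="session")
def trained_1p(small_cohort):
    """A 1p estimator trained on the small cohort (shared across tests)."""
    bags = [b for b, _ in small_cohort]
    fc = np.array([t.fc_1p for _, t in small_cohort])
    cfg = TrainConfig(N=10, max_epochs=30, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params, log = train_fc_estimator(bags[:40], fc[:40], bags[40:50], fc[40:50], cfg, arm="1p")
    return params, log


@pytest.fixture()
def random_params(rng):
    """Randomly initialized estimator parameters (D=8, N=3)."""
    return init_params("1p", feature_dim=8, N=3, rng=rng)
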