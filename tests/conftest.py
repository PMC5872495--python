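import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stackbench.datasets import SplitSpec, SyntheticConfig, generate_synthetic_dataset, split_replicate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_replicate():
    """One small synthetic replicate: (train, validation, test, reserve)."""
    cfg = SyntheticConfig(n_samples=400, n_features=20, seed=11)
    ds, weak, strong = generate_synthetic_dataset(cfg)
    spec = SplitSpec(n_train_init=60, n_validation=40, n_test=100)
    train, val, test, reserve = split_replicate(ds, spec, seed=5)
    return {
        "dataset": ds,
        "weak": weak,
        "strong": strong,
        "train": train,
        "validation": val,
        "test": test,
        "reserve": reserve,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
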