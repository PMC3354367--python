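import numpy as np
import pytest

from adaptraj import build_hepatic_model, run_multistart
from adaptraj.synthetic import (
    DEFAULT_MASK,
    generate_dataset,
    lxr_demo_dataset,
    make_ground_truth,
)


@pytest.fixture(scope="session")
def model():
    return build_hepatic_model()


@pytest.fixture(scope="session")
def truth():
    return make_ground_truth()


@pytest.fixture(scope="session")
def dataset(model, truth):
    """Default synthetic two-phenotype dataset (cv = 0.2, pool split masked)."""
    return generate_dataset(model, truth, cv=0.2, seed=0, mask=DEFAULT_MASK)


@pytest.fixture(scope="session")
def tight_dataset(model, truth):
    """Near-noiseless dataset (cv = 1e-3) for sigma -> 0 limit checks."""
    return generate_dataset(model, truth, cv=1e-3, seed=0, mask=DEFAULT_MASK)


@pytest.fixture(scope="session")
def demo_dataset(model, truth):
    """Dataset anchored to the literature hepatic-TG and VLDL-diameter values."""
    return lxr_demo_dataset(model, cv=0.2, seed=0, truth=truth)


@pytest.fixture(scope="session")
def small_ensemble(model, dataset):
    """A quick multistart ensemble shared across tests (seeded)."""
    return run_multistart(model, dataset, "A", n_samples=400, n_top=8, seed=11)


@pytest.fixture(scope="session")
def demo_ensemble(model, demo_dataset):
    """Test-scale ensemble on the literature-anchored demo dataset."""
    return run_multistart(model, demo_dataset, "A", n_samples=2000, n_top=20, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
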