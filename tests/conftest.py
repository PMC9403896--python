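import numpy as np
import pytest

import emolearn as el


@pytest.fixture(scope="session")
def tiny_config():
    """A scaled-down training configuration for fast pipeline tests."""
    return {
        "generator": {"n_per_class": 8, "noise_sd": 0.2, "seed": 11},
        "ica": {"m": 6, "restarts": 2, "tol": 1e-3, "max_iter": 100},
        "boost": {"T": 5},
    }


@pytest.fixture(scope="session")
def tiny_artifacts(tiny_config):
    return el.run_training(tiny_config)


@pytest.fixture(scope="session")
def default_corpus():
    """The documented surrogate corpus: 5 classes x 50 images."""
    return el.generate_dataset(n_per_class=50, size=32, noise_sd=0.3, n_groups=5, seed=20220811)


@pytest.fixture(scope="session")
def default_artifacts():
    """Models trained with the default configuration (full surrogate corpus)."""
    return el.run_training()


@pytest.fixture(scope="session")
def benchmark_reports(default_corpus):
    """Held-out comparison of all methods on the surrogate corpus."""
    return el.evaluate(default_corpus, split_seed=20220811, ica_seed=20220811)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
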