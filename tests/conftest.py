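import numpy as np
import pytest

from sonotex.pipeline import extract_features
from sonotex.selection import SelectorConfig, chi2_nca_select
from sonotex.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny synthetic set for structural checks (3 images per class)."""
    return generate_dataset(SynthConfig(n_per_class=3, seed=1))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    X = extract_features(small_dataset.images)
    return X, small_dataset.labels


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The repo's fixed synthetic benchmark: 60 images per class at the
    default separability 0.7, seed 0."""
    return generate_dataset(SynthConfig(n_per_class=60, separability=0.7, seed=0))


@pytest.fixture(scope="session")
def benchmark_features(benchmark_dataset):
    X = extract_features(benchmark_dataset.images)
    return X, benchmark_dataset.labels


@pytest.fixture(scope="session")
def benchmark_selection(benchmark_features):
    X, y = benchmark_features
    return chi2_nca_select(X, y, SelectorConfig(), seed=0)
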