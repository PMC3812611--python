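import numpy as np
import pytest

import sfamtongue as st


@pytest.fixture(scope="session")
def separable_data() -> st.TongueDataset:
    """Default 48-assay campaign in the zero-noise, well-separated regime."""
    return st.generate_dataset(st.separable_config(seed=0))


@pytest.fixture(scope="session")
def benchmark_data() -> st.TongueDataset:
    """4 informative + 3 dead electrodes, every informative one necessary."""
    return st.generate_dataset(st.selection_benchmark_config())


@pytest.fixture(scope="session")
def noisy_data() -> st.TongueDataset:
    """Default campaign with reading noise (the realistic regime)."""
    return st.generate_dataset(st.TongueConfig(seed=3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_training_set(rng: np.random.Generator, n: int, d: int) -> st.TongueDataset:
    """Small random dataset for oracle-equivalence checks."""
    X = rng.uniform(-300.0, 300.0, size=(n, d))
    y = rng.integers(1, 4, size=n)
    y[0] = 1  # labels must start at a valid class
    groups = np.array([f"M{i // 2 + 1}" for i in range(n)])
    return st.TongueDataset(X=X, y=y, groups=groups)
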