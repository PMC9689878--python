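import numpy as np
import pytest

from spectrace.dataset import SpectralDataset, make_wavenumber_grid
from spectrace.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Compact generator config: 4 classes, 120-point grid, fast."""
    return SyntheticConfig(
        n_classes=4,
        class_sizes=None,
        samples_per_class=10,
        n_points=120,
        n_outliers=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, truth = generate_dataset(small_config)
    return dataset, truth


@pytest.fixture()
def toy_dataset():
    """Deterministic 6-sample, 12-point dataset with two labels."""
    rng = np.random.default_rng(42)
    grid = make_wavenumber_grid(9000, 5000, 12)
    X = rng.normal(1.0, 0.2, (6, 12))
    return SpectralDataset(
        grid=grid,
        absorbance=X,
        labels=np.array(["a", "a", "a", "b", "b", "b"]),
        sample_ids=np.array([f"s{i}" for i in range(6)], dtype=object),
    )
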