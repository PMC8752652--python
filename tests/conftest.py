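import numpy as np
import pytest

from mammofeat.io import RunConfig
from mammofeat.pipeline import extract_table
from mammofeat.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 10+10 synthetic cohort, shared across tests."""
    return generate_dataset(10, 10, master_seed=3)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return extract_table(small_dataset.to_lesion_samples())


@pytest.fixture(scope="session")
def benchmark_table():
    """The default 52/63 benchmark cohort's feature table (one extraction)."""
    cfg = RunConfig()
    dataset = generate_dataset(cfg.n_benign, cfg.n_malignant, master_seed=cfg.master_seed)
    return extract_table(dataset.to_lesion_samples(), levels=cfg.glcm_levels)


@pytest.fixture
def blob_mask():
    """An irregular but connected 64x64 test blob."""
    rng = np.random.default_rng(42)
    yy, xx = np.mgrid[:64, :64]
    mask = np.zeros((64, 64), bool)
    for _ in range(6):
        cy, cx = rng.integers(18, 46, size=2)
        r = rng.integers(6, 14)
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return mask
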