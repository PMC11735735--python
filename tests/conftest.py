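import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import hashdemux as hd

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> hd.TagCountMatrix:
    """3 tags x 4 cells with explicit zeros."""
    counts = np.array(
        [
            [5, 0, 12, 3],
            [0, 7, 1, 0],
            [2, 2, 0, 9],
        ]
    )
    return hd.TagCountMatrix(counts, ["HTO1", "HTO2", "HTO3"], ["c1", "c2", "c3", "c4"])


@pytest.fixture(scope="session")
def low_noise_dataset() -> hd.SimulatedDataset:
    """Default low-noise simulation: 5 tags, 1000 cells/tag, 10% doublets,
    2% cell-bound contamination, ambient max 100."""
    return hd.simulate_dataset(hd.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset() -> hd.SimulatedDataset:
    """Reduced-size simulation for faster clustering tests."""
    config = hd.SimulationConfig(n_tags=4, cells_per_tag=150, seed=3)
    return hd.simulate_dataset(config)
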