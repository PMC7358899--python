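import numpy as np
import pytest

from netanat.domain import SpatialDomain


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_box_3d():
    return SpatialDomain((100.0, 100.0, 100.0), extension_margin=0, trim_margin=0)


@pytest.fixture
def small_box_2d():
    return SpatialDomain((100.0, 100.0), extension_margin=0, trim_margin=0)


def brute_force_pairs(a: np.ndarray, b: np.ndarray, radius: float):
    """O(n*m) all-pairs oracle: (i, j) index pairs with ||a_i - b_j|| <= radius."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    i, j = np.nonzero(d <= radius)
    return set(zip(i.tolist(), j.tolist()))


def min_pairwise_distance(pts: np.ndarray) -> float:
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return float(d.min())
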