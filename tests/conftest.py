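import numpy as np
import pytest

from cakl.distance import distance_matrix
from cakl.featurize import FeatureConfig, representations
from cakl.synthetic import SyntheticConfig, simulate_families


@pytest.fixture(scope="session")
def family_dataset():
    """Four well-separated synthetic families pushed through featurization.

    Shared session-wide: simulate 4 families x 10 members (length 3000,
    substitution rate 0.01), featurize at k=4 defaults, and compute the
    composite distance matrix once.
    """
    cfg = SyntheticConfig(
        n_families=4, per_family=10, length=3000, substitution_rate=0.01, seed=11
    )
    records, labels = simulate_families(cfg)
    reps = representations(records, FeatureConfig())
    dm = distance_matrix(reps)
    return records, labels, reps, dm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_point_sets(rng, n_sets, max_n=10, max_coord=30):
    """Random strictly-increasing integer point clouds for oracle comparisons."""
    out = []
    for _ in range(n_sets):
        n = int(rng.integers(1, max_n + 1))
        pts = sorted(rng.choice(max_coord, size=n, replace=False).tolist())
        out.append([int(p) for p in pts])
    return out
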