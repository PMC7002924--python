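import numpy as np
import pytest

from mdimportance.featurization import FeatureMatrix, LabelSet, minmax_scale
from mdimportance.toy_model import ToyConfig, generate_frames, generate_system


@pytest.fixture(scope="session")
def small_toy():
    """A quick 30-atom, 2-state toy system with trajectory."""
    cfg = ToyConfig(
        n_atoms=30,
        n_states=2,
        n_important_per_state=5,
        n_frames_per_state=60,
        seed=42,
    )
    system = generate_system(cfg)
    return system, generate_frames(system)


@pytest.fixture(scope="session")
def default_toy():
    """A standard-size toy system (100 atoms, 3 states) at reduced frame count."""
    cfg = ToyConfig(n_frames_per_state=150, seed=7)
    system = generate_system(cfg)
    return system, generate_frames(system)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_feature_matrix(values, kind="cartesian", scaled=False, prescaled=False):
    """Helper: wrap a plain array with auto-generated descriptors.

    ``scaled`` applies min-max scaling; ``prescaled`` marks values already
    lying in [0, 1] as scaled without transforming them (so engineered
    variance structure is preserved).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if kind == "cartesian":
        descriptors = [(i // 3, "xyz"[i % 3]) for i in range(n)]
    else:
        descriptors = [(0, i + 1) for i in range(n)]
    fm = FeatureMatrix(values, descriptors, kind)
    if prescaled:
        fm.scaling = (np.zeros(n), np.ones(n))
        return fm
    return minmax_scale(fm) if scaled else fm


@pytest.fixture()
def two_cluster_data(rng):
    """Feature 0 separates two states; remaining features are noise."""
    n = 200
    y = rng.integers(0, 2, n)
    X = rng.uniform(0, 1, (n, 6))
    X[:, 0] = np.where(y == 0, rng.uniform(0, 0.25, n), rng.uniform(0.75, 1, n))
    fm = make_feature_matrix(X, scaled=True)
    return fm, LabelSet(y, 2)
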