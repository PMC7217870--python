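import numpy as np
import pytest

from gratjoy import (RatingEffectParams, generate_ratings,
                     generate_subject_design)
from gratjoy.images import VoxelGrid
from gratjoy.mvpa import FeatureMatrix


@pytest.fixture(scope="session")
def subject_design():
    return generate_subject_design(1, "A-B-B-A-A-B", seed=42)


@pytest.fixture(scope="session")
def default_params():
    return RatingEffectParams()


@pytest.fixture(scope="session")
def subject_ratings(subject_design, default_params):
    return generate_ratings(subject_design, default_params, seed=7)


def make_feature_matrix(X, n_subjects):
    """Wrap a (2 n_subjects, n_features) array as a FeatureMatrix with an
    arbitrary rectangular grid (one voxel per feature)."""
    n_feat = X.shape[1]
    shape = (n_feat, 1, 1)
    mask = np.ones(shape, bool)
    return FeatureMatrix(
        X=np.asarray(X, float), labels=np.tile([1, -1], n_subjects),
        subjects=np.repeat(np.arange(n_subjects), 2),
        voxel_index=np.argwhere(mask), grid=VoxelGrid(shape), mask=mask)


@pytest.fixture
def null_features_factory():
    def make(seed, n_subjects=30, n_features=200):
        rng = np.random.default_rng(seed)
        return make_feature_matrix(
            rng.standard_normal((2 * n_subjects, n_features)), n_subjects)
    return make


@pytest.fixture
def planted_features_factory():
    """Features with a consistent gratitude-minus-joy difference planted in
    the first ``n_signal`` features."""
    def make(seed, n_subjects=30, n_features=200, n_signal=12, delta=1.25):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((2 * n_subjects, n_features))
        X[0::2, :n_signal] += delta / 2.0
        X[1::2, :n_signal] -= delta / 2.0
        return make_feature_matrix(X, n_subjects)
    return make
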