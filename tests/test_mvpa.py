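"""Feature assembly, scaling, paired-t selection, SVM (QP oracle), LOPO-CV,
permutation counting and consensus weight maps."""

import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from gratjoy import mvpa as mv
from gratjoy.images import VoxelGrid, VoxelMap

from conftest import make_feature_matrix


# ---------------------------------------------------------------- assembling

def test_assemble_features_shapes_and_labels():
    grid = VoxelGrid((3, 3, 3))
    mask = np.zeros((3, 3, 3), bool)
    mask[:, 0, 0] = True       # 3 in-mask voxels
    rng = np.random.default_rng(0)
    g = {s: VoxelMap(rng.normal(size=(3, 3, 3)), grid) for s in range(5)}
    j = {s: VoxelMap(rng.normal(size=(3, 3, 3)), grid) for s in range(5)}
    fm = mv.assemble_features(g, j, VoxelMap(mask.astype(float), grid))
    assert fm.X.shape == (10, 3)
    assert list(fm.labels) == [1, -1] * 5
    assert fm.n_subjects == 5
    # identical maps for one subject -> identical rows, opposite labels
    j[3] = g[3]
    fm = mv.assemble_features(g, j, VoxelMap(mask.astype(float), grid))
    rows = np.flatnonzero(fm.subjects == 3)
    assert np.array_equal(fm.X[rows[0]], fm.X[rows[1]])
    assert fm.labels[rows[0]] != fm.labels[rows[1]]


def test_assemble_features_missing_subject_raises():
    grid = VoxelGrid((2, 2, 2))
    g = {1: VoxelMap(np.zeros((2, 2, 2)), grid)}
    with pytest.raises(ValueError):
        mv.assemble_features(g, {}, np.ones((2, 2, 2), bool))


# ------------------------------------------------------------------- scaling

def test_min_max_scaling_examples_and_oracle():
    train = np.array([[2.0], [4.0]])
    tr, te, scaler = mv.scale_features(train, np.array([[3.0], [5.0]]))
    assert te[0, 0] == pytest.approx(0.5)
    assert te[1, 0] == pytest.approx(1.5)   # no clipping outside [0, 1]
    rng = np.random.default_rng(1)
    train = rng.normal(size=(8, 5))
    test = rng.normal(size=(3, 5))
    tr, te, scaler = mv.scale_features(train, test)
    mn, mx = train.min(axis=0), train.max(axis=0)
    np.testing.assert_allclose(tr, (train - mn) / (mx - mn), atol=1e-12)
    np.testing.assert_allclose(te, (test - mn) / (mx - mn), atol=1e-12)


def test_zero_range_feature_maps_to_zero_with_flag():
    train = np.array([[1.0, 2.0], [1.0, 3.0]])
    tr, te, scaler = mv.scale_features(train, np.array([[7.0, 2.5]]))
    assert scaler.zero_range[0] and not scaler.zero_range[1]
    assert tr[:, 0].tolist() == [0.0, 0.0]
    assert te[0, 0] == 0.0


# ----------------------------------------------------------------- selection

def test_selection_matches_paired_t_oracle():
    rng = np.random.default_rng(2)
    n_pairs, n_feat = 5, 40
    X = rng.normal(size=(2 * n_pairs, n_feat))
    subjects = np.repeat(np.arange(n_pairs), 2)
    labels = np.tile([1, -1], n_pairs)
    keep = mv.select_features(X, subjects, labels, alpha=0.05)
    diffs = X[0::2] - X[1::2]
    t, p = stats.ttest_rel(X[0::2], X[1::2], axis=0)
    np.testing.assert_array_equal(keep, p < 0.05)


def test_selection_drops_label_identical_and_keeps_planted():
    rng = np.random.default_rng(3)
    n_pairs = 8
    X = rng.normal(size=(2 * n_pairs, 3), scale=0.01)
    X[:, 0] = np.repeat(rng.normal(size=n_pairs), 2)  # identical across labels
    X[0::2, 1] += 5.0                                 # planted difference
    subjects = np.repeat(np.arange(n_pairs), 2)
    labels = np.tile([1, -1], n_pairs)
    keep = mv.select_features(X, subjects, labels)
    assert not keep[0]
    assert keep[1]


def test_selection_requires_two_intact_pairs():
    X = np.zeros((2, 4))
    with pytest.raises(ValueError):
        mv.select_features(X, np.array([0, 0]), np.array([1, -1]))


# ----------------------------------------------------------------------- SVM

def test_two_point_svm_geometry():
    X = np.array([[1.0, 0.0], [-1.0, 0.0]])
    y = np.array([1, -1])
    w, b = mv.train_linear_classifier(X, y, C=1.0)
    assert np.sign(X @ w + b).tolist() == [1, -1]
    diff = X[0] - X[1]
    cos = w @ diff / (np.linalg.norm(w) * np.linalg.norm(diff))
    assert cos == pytest.approx(1.0, abs=1e-6)


def test_label_swap_negates_weights():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 4))
    y = np.tile([1, -1], 5)
    w1, b1 = mv.train_linear_classifier(X, y)
    w2, b2 = mv.train_linear_classifier(X, -y)
    np.testing.assert_allclose(w2, -w1, atol=1e-3)
    assert b2 == pytest.approx(-b1, abs=1e-3)


def _svm_dual_oracle(X, y, C=1.0):
    """Small quadratic program for the soft-margin SVM dual."""
    n = len(y)
    K = (X @ X.T) * np.outer(y, y)

    def neg_dual(a):
        return 0.5 * a @ K @ a - a.sum()

    cons = [{"type": "eq", "fun": lambda a: a @ y}]
    res = minimize(neg_dual, np.full(n, 0.1), bounds=[(0, C)] * n,
                   constraints=cons, method="SLSQP",
                   options={"ftol": 1e-12, "maxiter": 500})
    a = res.x
    w = (a * y) @ X
    on_margin = (a > 1e-6) & (a < C - 1e-6)
    sv = on_margin if on_margin.any() else a > 1e-6
    b = np.mean(y[sv] - X[sv] @ w)
    return w, b


def test_svm_matches_quadratic_program_oracle():
    X = np.array([[2.0, 1.0], [1.0, 2.0], [-1.0, -1.5], [-2.0, -0.5]])
    y = np.array([1, 1, -1, -1])
    w, b = mv.train_linear_classifier(X, y, C=1.0)
    w_qp, b_qp = _svm_dual_oracle(X, y, C=1.0)
    np.testing.assert_allclose(X @ w + b, X @ w_qp + b_qp, atol=1e-3)


def test_single_class_training_raises():
    with pytest.raises(ValueError):
        mv.train_linear_classifier(np.zeros((3, 2)), np.array([1, 1, 1]))


# ------------------------------------------------------------------- LOPO-CV

def test_huge_planted_signal_gives_perfect_accuracy(planted_features_factory):
    fm = planted_features_factory(0, n_subjects=10, n_features=30,
                                  n_signal=10, delta=20.0)
    cv = mv.run_lopo_cv(fm)
    assert cv.accuracy == 1.0
    assert cv.specificity == 1.0 and cv.sensitivity == 1.0


def test_lopo_runs_one_fold_per_subject(null_features_factory):
    fm = null_features_factory(1, n_subjects=30, n_features=50)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = mv.run_lopo_cv(fm)
    assert len(cv.folds) == 30
    assert sum(len(f.predictions) for f in cv.folds) == 60


def test_accuracy_is_mean_of_specificity_and_sensitivity(
        null_features_factory):
    fm = null_features_factory(2, n_subjects=12, n_features=40)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = mv.run_lopo_cv(fm)
    assert cv.accuracy == pytest.approx(
        (cv.specificity + cv.sensitivity) / 2)


def test_null_accuracy_is_unbiased_across_seeds(null_features_factory):
    accs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(25):
            accs.append(mv.run_lopo_cv(
                null_features_factory(s, n_subjects=12,
                                      n_features=60)).accuracy)
    # mean accuracy consistent with chance (SE ~ 0.13 / 5)
    assert abs(np.mean(accs) - 0.5) < 0.08


def test_no_leakage_from_held_out_subject(null_features_factory):
    """Corrupting the held-out subject's values leaves every fold training
    artifact bit-identical."""
    fm = null_features_factory(3, n_subjects=8, n_features=40)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv1 = mv.run_lopo_cv(fm)
        for s in range(8):
            corrupted = null_features_factory(3, n_subjects=8, n_features=40)
            corrupted.X[corrupted.subjects == s] = 1e6
            cv2 = mv.run_lopo_cv(corrupted)
            f1 = cv1.folds[s]
            f2 = cv2.folds[s]
            assert np.array_equal(f1.selected, f2.selected)
            assert np.array_equal(f1.weights, f2.weights)
            assert f1.bias == f2.bias
            assert np.array_equal(f1.scaler.min_, f2.scaler.min_)
            assert np.array_equal(f1.scaler.range_, f2.scaler.range_)


# --------------------------------------------------------------- permutation

def test_permutation_p_counting_rules(null_features_factory):
    fm = null_features_factory(4, n_subjects=8, n_features=30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mv.permutation_test(fm, observed_accuracy=1.01, n_perm=20,
                                  seed=0)
    assert res.p == 0.0     # nothing exceeds an impossible accuracy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_c = mv.permutation_test(fm, observed_accuracy=1.01, n_perm=20,
                                    seed=0, conservative=True)
    assert res_c.p == pytest.approx(1 / 21)
    # enumeration oracle: p equals the hand count over recorded accuracies
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res2 = mv.permutation_test(fm, observed_accuracy=0.5, n_perm=20,
                                   seed=1)
    assert res2.p == pytest.approx(
        np.sum(res2.null_accuracies > 0.5) / 20)


def test_observed_at_null_median_gives_half(null_features_factory):
    fm = null_features_factory(5, n_subjects=8, n_features=30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mv.permutation_test(fm, observed_accuracy=None, n_perm=30,
                                  seed=2)
        med = float(np.median(res.null_accuracies))
        res_med = mv.permutation_test(fm, observed_accuracy=med, n_perm=30,
                                      seed=2)
    assert 0.2 < res_med.p < 0.8


def test_within_subject_scheme_preserves_pairing(null_features_factory):
    fm = null_features_factory(6, n_subjects=6, n_features=20)
    rng = np.random.default_rng(0)
    perm = mv._permute_labels(fm.labels, fm.subjects, rng, "within_subject")
    for s in range(6):
        pair = perm[fm.subjects == s]
        assert sorted(pair) == [-1, 1]


# ----------------------------------------------------------------- weight map

def _fold(selected, weights):
    return mv.FoldResult(held_out=0, selected=np.asarray(selected, bool),
                         scaler=None, weights=np.asarray(weights, float),
                         bias=0.0, decision=np.zeros(2),
                         true_labels=np.array([1, -1]),
                         predictions=np.array([1, -1]))


def test_consensus_requires_every_fold():
    shape = (3, 1, 1)
    grid = VoxelGrid(shape)
    mask = np.ones(shape, bool)
    vi = np.argwhere(mask)
    folds = [_fold([True, True, False], [0.2, -0.2]),
             _fold([True, False, False], [0.4])]
    wm = mv.consensus_weight_map(folds, grid, vi, mask, min_cluster=1)
    assert wm.consensus.tolist() == [True, False, False]
    assert wm.map.data[0, 0, 0] == pytest.approx((0.2 + 0.4) / 2)
    assert wm.map.data[1, 0, 0] == 0.0


def test_mean_absolute_weight():
    shape = (1, 1, 1)
    grid = VoxelGrid(shape)
    mask = np.ones(shape, bool)
    folds = [_fold([True], [0.2]), _fold([True], [-0.2])]
    wm = mv.consensus_weight_map(folds, grid, np.argwhere(mask), mask,
                                 min_cluster=1)
    assert wm.map.data[0, 0, 0] == pytest.approx(0.2)


def test_small_blobs_are_omitted_from_cluster_table():
    shape = (10, 1, 1)
    grid = VoxelGrid(shape)
    mask = np.ones(shape, bool)
    vi = np.argwhere(mask)
    sel = np.zeros(10, bool)
    sel[:4] = True   # a 4-voxel consensus blob
    folds = [_fold(sel, [0.1] * 4), _fold(sel, [0.2] * 4)]
    wm = mv.consensus_weight_map(folds, grid, vi, mask, min_cluster=5)
    assert wm.consensus.sum() == 4
    assert len(wm.clusters) == 0
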