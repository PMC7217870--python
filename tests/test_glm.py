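"""HRF, design matrices, serial orthogonalization (QR oracle), OLS fitting."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from gratjoy import glm as G
from gratjoy import build_model1, build_model2, canonical_hrf, contrast_image, fit_glm
from gratjoy.bold import synthesize_motion
from gratjoy.design import condition_names
from gratjoy.images import VoxelGrid, VoxelMap


# ----------------------------------------------------------------------- HRF

def test_hrf_has_single_positive_lobe_and_undershoot():
    h = canonical_hrf(2.3, oversampling=16)
    dt = 2.3 / 16
    t = np.arange(len(h)) * dt
    assert h.max() == pytest.approx(1.0)
    assert 4.0 < t[np.argmax(h)] < 7.0
    assert h.min() < 0
    assert 12.0 < t[np.argmin(h)] < 20.0
    assert h.sum() * dt > 0


def test_hrf_vanishes_by_30s_against_closed_form():
    # evaluate the double-gamma closed form directly at t = 30 s
    t = 30.0
    val = (np.exp(5 * np.log(t) - t - gammaln(6.0))
           - np.exp(15 * np.log(t) - t - gammaln(16.0)) / 6.0)
    peak = 0.20756  # max of the unnormalized double gamma near t = 5.17 s
    assert abs(val / peak) < 1e-3
    h = canonical_hrf(1.0, oversampling=10, time_length=32.0)
    assert abs(h[int(30.0 / 0.1)]) < 1e-3


def test_impulse_convolution_reproduces_kernel():
    tr, os_ = 1.0, 8
    kernel = canonical_hrf(tr, os_)
    dt = tr / os_
    reg = G._convolve_events([0.0], [dt], [1.0], 40, tr, os_, kernel)
    expected = kernel[::os_]
    np.testing.assert_allclose(reg[:len(expected)], expected, atol=1e-12)
    np.testing.assert_allclose(reg[len(expected):], 0.0, atol=1e-12)


# ------------------------------------------------------------------- Model 1

def test_model1_structure(subject_design, subject_ratings):
    motion = [synthesize_motion(r.n_volumes, seed=k)
              for k, r in enumerate(subject_design.runs)]
    X = build_model1(subject_design, subject_ratings, motion=motion)
    conds = [n for n in X.names if n in condition_names()]
    assert len(conds) == 18
    nuisance = [n for n in X.names if n.startswith(("rating_order", "motion"))]
    assert len(nuisance) == 7
    assert sum(n.startswith("intercept_run") for n in X.names) == 6
    assert X.n_timepoints == 6 * 145
    # no all-zero regressor
    assert all(np.any(X.matrix[:, k]) for k in range(X.matrix.shape[1]))


def test_model1_condition_support_follows_schedule(subject_design,
                                                   subject_ratings):
    X = build_model1(subject_design, subject_ratings,
                     include_rating_order=False)
    events = G.rating_events(subject_design, subject_ratings)
    name = "gratitude_strong_high"
    col = X.column(name)
    sel = events[(events["emotion"] == "gratitude")
                 & (events["intention"] == "strong")
                 & (events["value"] == "high")]
    tr = 2.3
    support = np.zeros(X.n_timepoints, bool)
    for _, ev in sel.iterrows():
        start = (int(ev["run"]) - 1) * 145
        a = int(ev["onset"] / tr)
        b = int((ev["onset"] + ev["duration"] + 32.0) / tr) + 1
        support[start + a:start + min(b, 145)] = True
    assert np.abs(col[~support]).max() < 1e-6 * np.abs(col).max()


def test_model1_determinism(subject_design, subject_ratings):
    X1 = build_model1(subject_design, subject_ratings)
    X2 = build_model1(subject_design, subject_ratings)
    assert X1.names == X2.names
    assert np.array_equal(X1.matrix, X2.matrix)


# ------------------------------------------------------------------- Model 2

def test_quadratic_code_is_square_of_linear():
    ev = pd.DataFrame({
        "intention": ["strong", "weak", "no"], "value": ["high", "low", "zero"],
        "rating": [3.0, 2.0, 1.0]})
    vals = G.modulator_values(ev)
    np.testing.assert_array_equal(vals[:, 1], [1, 0, -1])
    np.testing.assert_array_equal(vals[:, 2], [1, 0, 1])
    np.testing.assert_array_equal(vals[:, 3], [1, 0, -1])


def test_serial_orthogonalization_is_sequentially_orthogonal():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(24, 4))
    o = G.serially_orthogonalize(v)
    assert np.abs(o.sum(axis=0)).max() < 1e-10   # centered
    for k in range(4):
        for j in range(k):
            assert abs(o[:, k] @ o[:, j]) < 1e-10


@pytest.mark.parametrize("seed", range(6))
def test_serial_orthogonalization_matches_qr_oracle(seed):
    """Classical Gram-Schmidt on [1, m1..m4] via QR as independent oracle."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 30))
    v = rng.normal(size=(n, 4))
    ours = G.serially_orthogonalize(v)
    M = np.column_stack([np.ones(n), v])
    Q, R = np.linalg.qr(M)
    expected = Q[:, 1:] * np.diag(R)[1:]
    np.testing.assert_allclose(ours, expected, atol=1e-10)


def test_model2_block_layout_and_event_orthogonality(subject_design,
                                                     subject_ratings):
    X = build_model2(subject_design, subject_ratings)
    expected = [f"{e}_onset" for e in ("gratitude", "joy")]
    assert [n for n in X.names if n.endswith("_onset")] == expected
    assert sum("_x_" in n for n in X.names) == 8
    assert X.orthogonalized
    for e in ("gratitude", "joy"):
        ev = G.rating_events(subject_design, subject_ratings)
        ev = ev[ev["emotion"] == e].sort_values(["run", "onset"])
        mods = G.serially_orthogonalize(G.modulator_values(ev))
        gram = mods.T @ mods
        off = np.abs(gram - np.diag(np.diag(gram)))
        assert off.max() < 1e-10


def test_constant_modulator_dropped_with_warning(subject_design,
                                                 subject_ratings):
    # force every rating to the same value -> emotion_rating has no variance
    flat = [r.__class__(**{**r.__dict__, "gratitude": 2, "joy": 2})
            for r in subject_ratings]
    with pytest.warns(UserWarning, match="constant modulator"):
        X = build_model2(subject_design, flat)
    assert "gratitude_x_emotion_rating" not in X.names
    assert "gratitude_x_intention_linear" in X.names


# ------------------------------------------------------------------- fitting

def _toy_fit(seed=0, n_t=40, shape=(3, 3, 3), noise=0.0):
    rng = np.random.default_rng(seed)
    X = G.DesignMatrix(
        matrix=np.column_stack([rng.normal(size=(n_t, 2)), np.ones(n_t)]),
        names=["a", "b", "intercept"], tr=1.0, run_volumes=[n_t])
    mask = np.ones(shape, bool)
    mask[0, 0, 0] = False
    betas = rng.normal(size=(3,) + shape)
    bold = np.einsum("tp,p...->...t", X.matrix,
                     betas) + noise * rng.standard_normal(shape + (n_t,))
    return X, mask, betas, bold


def test_noiseless_fit_recovers_betas_exactly():
    X, mask, betas, bold = _toy_fit()
    fit = fit_glm(bold, X, mask)
    for k, name in enumerate(X.names):
        bm = fit.beta_map(name)
        np.testing.assert_allclose(bm.data[mask], betas[k][mask], atol=1e-8)
        assert np.isnan(bm.data[0, 0, 0])  # out-of-mask voxel has no value
    assert fit.df == 40 - 3


def test_ols_beta_covariance_matches_closed_form():
    """White-noise fits: empirical beta covariance vs sigma^2 (X'X)^-1."""
    rng = np.random.default_rng(1)
    n_t, sigma = 60, 2.0
    X = G.DesignMatrix(
        matrix=np.column_stack([rng.normal(size=(n_t, 2)), np.ones(n_t)]),
        names=["a", "b", "c"], tr=1.0, run_volumes=[n_t])
    shape = (20, 20, 10)   # 4000 independent replicate voxels
    bold = sigma * rng.standard_normal(shape + (n_t,))
    fit = fit_glm(bold, X, np.ones(shape, bool))
    emp = np.cov(fit.betas)
    theory = sigma ** 2 * np.linalg.inv(X.matrix.T @ X.matrix)
    np.testing.assert_allclose(emp, theory, atol=0.15 * np.abs(theory).max())


def test_rank_deficient_design_warns_but_keeps_unique_betas(subject_design,
                                                            subject_ratings):
    """The rating-order indicator is collinear with run intercepts; the
    condition betas are nonetheless unique (deficiency is nuisance-only)."""
    X_full = build_model1(subject_design, subject_ratings)
    X_clean = build_model1(subject_design, subject_ratings,
                           include_rating_order=False)
    rng = np.random.default_rng(2)
    shape = (3, 3, 3)
    amps = rng.normal(size=(18,) + shape)
    cond = condition_names()
    bold = np.einsum("tp,p...->...t",
                     np.column_stack([X_clean.column(c) for c in cond]), amps)
    mask = np.ones(shape, bool)
    with pytest.warns(UserWarning, match="rank-deficient"):
        fit_full = fit_glm(bold, X_full, mask)
    fit_clean = fit_glm(bold, X_clean, mask)
    for c in cond:
        np.testing.assert_allclose(fit_full.beta_map(c).data,
                                   fit_clean.beta_map(c).data, atol=1e-8)


def test_fit_glm_shape_mismatch_raises():
    X, mask, _, bold = _toy_fit()
    with pytest.raises(ValueError):
        fit_glm(bold[..., :-1], X, mask)


# ----------------------------------------------------------------- contrasts

def test_contrast_unit_vector_returns_that_beta_map():
    X, mask, betas, bold = _toy_fit()
    fit = fit_glm(bold, X, mask)
    cm = contrast_image(fit, {"b": 1.0})
    np.testing.assert_allclose(cm.data[mask], betas[1][mask], atol=1e-8)
    zero = contrast_image(fit, np.zeros(3))
    assert np.nanmax(np.abs(zero.data)) == 0.0


def test_difference_contrast_equals_two_pass_oracle(subject_design,
                                                    subject_ratings):
    """gratitude-minus-joy contrast equals averaging the gratitude beta
    maps and the joy beta maps separately, then subtracting."""
    rng = np.random.default_rng(3)
    shape = (3, 3, 3)
    X = build_model1(subject_design, subject_ratings,
                     include_rating_order=False)
    cond = condition_names()
    amps = rng.normal(size=(18,) + shape)
    bold = np.einsum("tp,p...->...t",
                     np.column_stack([X.column(c) for c in cond]), amps)
    fit = fit_glm(bold, X, np.ones(shape, bool))
    weights = {c: (1 / 9 if c.startswith("gratitude") else -1 / 9)
               for c in cond}
    cmap = contrast_image(fit, weights)
    g = np.mean([fit.beta_map(c).data for c in cond
                 if c.startswith("gratitude")], axis=0)
    j = np.mean([fit.beta_map(c).data for c in cond
                 if c.startswith("joy")], axis=0)
    np.testing.assert_allclose(cmap.data, g - j, atol=1e-8)


def test_contrast_length_mismatch_raises():
    X, mask, _, bold = _toy_fit()
    fit = fit_glm(bold, X, mask)
    with pytest.raises(ValueError):
        contrast_image(fit, np.ones(5))
    with pytest.raises(ValueError):
        contrast_image(fit, {"nonexistent": 1.0})
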