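"""Scaling, PCA and OPLS-DA against independent oracles and identities."""

import numpy as np
import pytest

from benchnmr.multivariate import (OPLSModel, fit_oplsda, fit_pca,
                                   permutation_q2, s_line, scale_columns,
                                   venetian_blind_folds, vip_scores)


def test_pareto_scaling_hand_example():
    """Column [1, 3]: mean 2, sd sqrt(2), scaled values +-1/2^(1/4)."""
    sm = scale_columns(np.array([[1.0], [3.0]]), "pareto")
    assert sm.means[0] == pytest.approx(2.0)
    assert sm.scales[0] == pytest.approx(2.0 ** 0.25)
    assert sm.values[:, 0] == pytest.approx([-1 / 2**0.25, 1 / 2**0.25])


def test_uv_scaled_columns_have_unit_sd():
    rng = np.random.default_rng(0)
    sm = scale_columns(rng.normal(3.0, 2.5, (40, 5)), "uv")
    assert sm.values.std(axis=0, ddof=1) == pytest.approx(np.ones(5))


def test_constant_column_is_centered_with_warning():
    X = np.column_stack([np.arange(6.0), np.full(6, 2.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        sm = scale_columns(X, "pareto")
    assert sm.zero_variance_columns == [1]
    assert np.all(sm.values[:, 1] == 0.0)


def test_scaling_reconstruction_is_lossless():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 3, (15, 8))
    for mode in ("pareto", "uv", "none"):
        sm = scale_columns(X, mode)
        assert np.max(np.abs(sm.reconstruct() - X)) < 1e-10


def test_single_row_rejected():
    with pytest.raises(ValueError):
        scale_columns(np.ones((1, 3)))


def test_rank1_matrix_puts_all_variance_on_pc1():
    u = np.arange(1.0, 7.0)[:, None]
    v = np.array([[2.0, -1.0, 0.5]])
    model = fit_pca(u @ v, n_components=2)
    assert model.explained_variance_fraction[0] == pytest.approx(1.0)


def test_pca_matches_sklearn_oracle_up_to_sign():
    """Random 10 x 20 matrices against scikit-learn's PCA as the oracle."""
    from sklearn.decomposition import PCA as SkPCA
    rng = np.random.default_rng(42)
    for _ in range(20):
        X = rng.normal(0, 1, (10, 20))
        model = fit_pca(scale_columns(X, "none"), n_components=3)
        sk = SkPCA(n_components=3, svd_solver="full").fit(X)
        scores_sk = sk.transform(X)
        for k in range(3):
            sign = np.sign(model.loadings[:, k] @ sk.components_[k])
            assert np.allclose(model.loadings[:, k],
                               sign * sk.components_[k], atol=1e-8)
            assert np.allclose(model.scores[:, k], sign * scores_sk[:, k],
                               atol=1e-8)


def test_pca_scores_are_uncorrelated():
    rng = np.random.default_rng(3)
    model = fit_pca(scale_columns(rng.normal(0, 1, (30, 12)), "uv"), 4)
    cov = model.scores.T @ model.scores
    off = cov - np.diag(np.diag(cov))
    assert np.max(np.abs(off)) < 1e-8


def test_pca_component_bounds():
    with pytest.raises(ValueError):
        fit_pca(np.zeros((5, 3)), n_components=5)


def _nipals_pls1(X, y, tol=1e-12, max_iter=500):
    """Independent single-component PLS1 oracle (classic NIPALS)."""
    w = X.T @ y
    w = w / np.linalg.norm(w)
    for _ in range(max_iter):
        t = X @ w
        c = (y @ t) / (t @ t)
        w_new = X.T @ y / np.linalg.norm(X.T @ y)
        if np.linalg.norm(w_new - w) < tol:
            break
        w = w_new
    t = X @ w
    p = X.T @ t / (t @ t)
    c = (y @ t) / (t @ t)
    return w, t, p, c


def _two_group_data(n=28, p=40, delta=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    X[y == "b", :5] += delta
    return X, y


def test_oplsda_without_orthogonal_components_equals_pls1():
    X, y = _two_group_data(delta=1.0)
    sm = scale_columns(X, "uv")
    model = fit_oplsda(sm, y, n_ortho=0)
    yc = np.where(y == "b", 1.0, -1.0)
    yc -= yc.mean()
    w_o, t_o, p_o, c_o = _nipals_pls1(sm.values, yc)
    sign = np.sign(w_o @ model.weights_pred)
    assert np.allclose(model.weights_pred, sign * w_o, atol=1e-8)
    assert np.allclose(model.scores_pred, sign * t_o, atol=1e-8)
    assert model.c_pred * sign == pytest.approx(c_o, abs=1e-8)


def test_separated_groups_give_high_q2():
    X, y = _two_group_data(delta=8.0, seed=5)
    model = fit_oplsda(scale_columns(X, "uv"), y, n_ortho=1)
    assert model.q2 > 0.9
    assert model.q2 <= model.r2y


def test_orthogonal_scores_are_orthogonal_to_predictive():
    X, y = _two_group_data(delta=2.0, seed=7)
    model = fit_oplsda(scale_columns(X, "pareto"), y, n_ortho=2)
    for k in range(model.scores_ortho.shape[1]):
        assert abs(model.scores_pred @ model.scores_ortho[:, k]) < 1e-8


def test_q2_never_exceeds_r2y_across_conditions():
    for seed in range(8):
        for delta in (0.5, 1.5, 3.0):
            X, y = _two_group_data(delta=delta, seed=seed)
            m = fit_oplsda(scale_columns(X, "pareto"), y, n_ortho=1)
            assert m.q2 <= m.r2y + 1e-12


def test_q2_invariant_to_sample_order_given_fold_assignment():
    X, y = _two_group_data(delta=2.0, seed=2)
    sm = scale_columns(X, "uv")
    folds = venetian_blind_folds(len(y), 7)
    m1 = fit_oplsda(sm, y, fold_assignment=folds)
    perm = np.random.default_rng(0).permutation(len(y))
    m2 = fit_oplsda(scale_columns(X[perm], "uv"), y[perm],
                    fold_assignment=folds[perm])
    assert m1.q2 == pytest.approx(m2.q2, abs=1e-10)


def test_permuted_labels_degrade_q2():
    X, y = _two_group_data(delta=3.0, seed=9)
    sm = scale_columns(X, "pareto")
    true_q2 = fit_oplsda(sm, y, n_ortho=1).q2
    perm = permutation_q2(sm, y, n_ortho=1, n_permutations=100, seed=0)
    assert np.mean(perm < true_q2) >= 0.95


def test_small_class_is_cv_infeasible():
    X = np.random.default_rng(0).normal(0, 1, (5, 4))
    y = np.array(["a", "a", "a", "a", "b"])
    with pytest.raises(ValueError, match="< 2 members"):
        fit_oplsda(scale_columns(X, "uv"), y)


def test_vip_identities():
    X, y = _two_group_data(delta=2.0, seed=11)
    model = fit_oplsda(scale_columns(X, "pareto"), y)
    vip = vip_scores(model)
    p = X.shape[1]
    assert np.sum(vip**2) == pytest.approx(p, abs=1e-8)
    # symmetric weights -> all VIP exactly 1
    sym = OPLSModel(model.scores_pred, model.loadings_pred,
                    np.full(p, 1 / np.sqrt(p)), model.c_pred,
                    model.scores_ortho, model.loadings_ortho,
                    model.weights_ortho, 0, 0, 0, model.y, model.classes)
    assert vip_scores(sym) == pytest.approx(np.ones(p))


def test_single_informative_variable_vip_approaches_sqrt_p():
    rng = np.random.default_rng(13)
    n, p = 60, 25
    y = np.array(["a"] * 30 + ["b"] * 30)
    X = rng.normal(0, 1e-6, (n, p))
    X[:, 4] = (y == "b") * 2.0 + rng.normal(0, 0.01, n)
    model = fit_oplsda(scale_columns(X, "none"), y, n_ortho=0)
    vip = vip_scores(model)
    assert vip[4] == pytest.approx(np.sqrt(p), rel=1e-3)


def test_sline_trivial_geometry():
    X, y = _two_group_data(delta=2.0, seed=17)
    sm = scale_columns(X, "uv")
    model = fit_oplsda(sm, y)
    t = model.scores_pred
    # a variable equal to the score has correlation 1
    X2 = np.column_stack([sm.values, t])
    cov, corr = s_line(model, X2)
    assert corr[-1] == pytest.approx(1.0)
    # a variable orthogonal to the score has zero covariance
    u = np.random.default_rng(0).normal(0, 1, t.size)
    u -= u.mean()
    u -= (u @ t) / (t @ t) * t
    X3 = np.column_stack([sm.values, u])
    cov3, _ = s_line(model, X3)
    assert abs(cov3[-1]) < 1e-10


def test_predictive_score_is_positive_for_positive_class():
    X, y = _two_group_data(delta=3.0, seed=19)
    model = fit_oplsda(scale_columns(X, "uv"), y)
    # 'b' is the lexicographically larger class -> positive orientation
    assert model.scores_pred[np.asarray(y) == "b"].mean() > 0
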