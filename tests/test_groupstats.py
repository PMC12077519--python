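"""PCA, Hotelling T², CVA, typicality probabilities, LOO classification."""

import numpy as np
import pytest
from scipy import stats

import phalanxmap as pm
from phalanxmap.groupstats import (assemble_matrix, cva, hotelling_one_sample,
                                   loo_classification, pca, typicality)

from test_cartography import const_map


def _maps(values, labels):
    maps = []
    for v in values:
        m = pm.standardize_map(const_map(1.0))
        m.values = np.full((97, 50), float(v)) if np.isscalar(v) else v
        maps.append(m)
    return assemble_matrix(maps, labels)


def test_assemble_constant_maps_rows():
    sm = _maps([1.0, 3.0, 2.0], ["a", "a", "b"])
    assert sm.X.shape == (3, 4850)
    assert np.allclose(sm.X[0], 1.0)
    assert np.allclose(sm.X[1], 3.0)
    assert sm.n_imputed == 0


def test_assemble_imputes_flagged_cells_with_group_mean():
    maps, labels = [], []
    for i in range(10):
        m = pm.standardize_map(const_map(2.0))
        maps.append(m)
        labels.append("g")
    flagged = maps[0]
    flagged.values[0, :5] = 99.0
    flagged.mask[0, :5] = True
    sm = assemble_matrix(maps, labels)
    assert sm.n_imputed == 5
    assert np.allclose(sm.X[0, :5], 2.0 / 40.0)   # replaced by group column mean


def test_assemble_row_order_follows_input_order():
    sm1 = _maps([1.0, 2.0, 3.0], ["a", "a", "b"])
    m_vals = [3.0, 1.0, 2.0]
    sm2 = _maps(m_vals, ["b", "a", "a"])
    assert np.allclose(sm2.X[:, 0], m_vals)
    assert sm2.labels == ["b", "a", "a"]


def test_assemble_rejects_unstandardized():
    with pytest.raises(ValueError, match="standardized"):
        assemble_matrix([const_map(1.0)] * 3, ["a", "a", "b"])


def test_pca_rank_one_data():
    rng = np.random.default_rng(0)
    direction = rng.normal(size=20)
    X = np.outer(rng.normal(size=8), direction) + 5.0
    model = pca(X)
    assert model.eigenvalues[0] > 1e-6
    assert np.all(model.eigenvalues[1:] < 1e-10 * model.eigenvalues[0])


def test_pca_full_reconstruction():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 6))
    model = pca(X)
    recon = model.mean + model.scores @ model.components
    assert np.allclose(recon, X, atol=1e-8)


def test_pca_matches_sklearn_oracle():
    from sklearn.decomposition import PCA as SkPCA
    rng = np.random.default_rng(2)
    X = rng.normal(size=(15, 8)) @ np.diag([5, 3, 2, 1, 1, 0.5, 0.2, 0.1])
    ours = pca(X, r=4)
    ref = SkPCA(n_components=4).fit(X)
    assert np.allclose(ours.eigenvalues[:4], ref.explained_variance_, rtol=1e-8)
    for j in range(4):
        cos = abs(np.dot(ours.components[j], ref.components_[j]))
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_pca_scores_centered_and_variance_matches_eigenvalue():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 10))
    model = pca(X, r=5)
    assert np.allclose(model.scores.mean(axis=0), 0.0, atol=1e-8)
    assert np.allclose(model.scores.var(axis=0, ddof=1), model.eigenvalues[:5],
                       rtol=1e-6)
    G = model.components @ model.components.T
    assert np.allclose(G, np.eye(5), atol=1e-8)


def test_pca_invariant_to_constant_offset_map():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(12, 30))
    m1 = pca(X, r=3)
    m2 = pca(X + 7.5, r=3)
    assert np.allclose(m1.scores, m2.scores, atol=1e-8)


def test_pca_separates_dorsal_amplitude_groups():
    """Two generator groups differing only in dorsal thickening separate on PC1
    by more than 3 pooled within-group standard deviations."""
    sds = {"dorsal_amp": 0.1}
    base_a = pm.SyntheticPhalanxSpec(thickness_field=pm.ThicknessFieldSpec(
        t0=1.2, dorsal_amp=0.4))
    base_b = pm.SyntheticPhalanxSpec(thickness_field=pm.ThicknessFieldSpec(
        t0=1.2, dorsal_amp=1.2))
    cohort = pm.generate_cohort([("a", base_a, sds), ("b", base_b, sds)],
                                n_per_group=6, seed=17)
    maps, labels = [], []
    for pair, _, label in cohort:
        maps.append(pm.standardize_map(pm.compute_thickness_map(pair)))
        labels.append(label)
    sm = assemble_matrix(maps, labels)
    model = pca(sm, r=3)
    pc1 = model.scores[:, 0]
    a = pc1[np.array(labels) == "a"]
    b = pc1[np.array(labels) == "b"]
    pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    assert abs(a.mean() - b.mean()) > 3 * pooled_sd


def test_hotelling_at_sample_mean_is_zero():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 3))
    res = hotelling_one_sample(X, X.mean(axis=0))
    assert res.T2 == pytest.approx(0.0, abs=1e-18)
    assert res.p_value == pytest.approx(1.0)


def test_hotelling_univariate_equals_squared_t():
    rng = np.random.default_rng(6)
    x = rng.normal(2.0, 1.5, size=(25, 1))
    res = hotelling_one_sample(x, np.array([1.0]))
    t, p = stats.ttest_1samp(x[:, 0], 1.0)
    assert res.T2 == pytest.approx(t ** 2, rel=1e-10)
    assert res.p_value == pytest.approx(p, rel=1e-10)


def test_hotelling_affine_invariance():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(15, 3))
    target = np.array([0.3, -0.2, 0.5])
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    b = rng.normal(size=3)
    r1 = hotelling_one_sample(X, target)
    r2 = hotelling_one_sample(X @ A.T + b, A @ target + b)
    assert r1.T2 == pytest.approx(r2.T2, rel=1e-8)


def test_hotelling_type_I_error_calibrated():
    rng = np.random.default_rng(8)
    mu = np.array([1.0, 2.0, 3.0])
    cov = np.diag([1.0, 2.0, 0.5])
    rejections = sum(
        hotelling_one_sample(rng.multivariate_normal(mu, cov, size=20), mu).p_value < 0.05
        for _ in range(2000))
    assert 0.04 <= rejections / 2000 <= 0.06


def test_cva_axis_count_and_whitening():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(40, 3))
    labels = (["a"] * 10 + ["b"] * 10 + ["c"] * 10 + ["d"] * 10)
    X[10:20] += [3, 0, 0]
    X[20:30] += [0, 3, 0]
    X[30:] += [0, 0, 3]
    model = cva(X, labels)
    assert model.n_axes == 3
    # pooled within-group covariance is the identity in canonical space
    Sw_canon = model.axes.T @ model.pooled_within_cov @ model.axes
    assert np.allclose(Sw_canon, np.eye(3), atol=1e-8)


def test_cva_first_axis_aligns_with_separation():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(40, 3))
    sep = np.array([1.0, 0.0, 0.0])
    X[20:] += 10 * sep
    model = cva(X, ["a"] * 20 + ["b"] * 20)
    axis = model.axes[:, 0] / np.linalg.norm(model.axes[:, 0])
    assert abs(np.dot(axis, sep)) > 0.99


def test_cva_permuted_labels_collapse_eigenvalues():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(40, 3))
    X[20:] += [4, 0, 0]
    labels = ["a"] * 20 + ["b"] * 20
    real_ev = cva(X, labels).eigenvalues[0]
    perm_evs = []
    for _ in range(200):
        perm = list(rng.permutation(labels))
        perm_evs.append(cva(X, perm).eigenvalues[0])
    assert real_ev > np.quantile(perm_evs, 0.95)


def test_typicality_centroid_and_chi2_identity():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(30, 3))
    labels = ["a"] * 15 + ["b"] * 15
    X[15:] += [5, 0, 0]
    model = cva(X, labels)
    centroid_pc = X[np.array(labels) == "a"].mean(axis=0)
    # specimen exactly at the group centroid
    res = typicality(model, centroid_pc, "a")
    assert res.D2 == pytest.approx(0.0, abs=1e-16)
    assert res.probability == pytest.approx(1.0)
    # chi-square identity: D2 at the 95th percentile -> probability 0.05
    assert stats.chi2.sf(7.815, 3) == pytest.approx(0.05, abs=1e-3)


def test_typicality_strictly_decreasing_in_distance():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(30, 2))
    labels = ["a"] * 15 + ["b"] * 15
    X[15:] += [6, 0]
    model = cva(X, labels)
    centroid = X[:15].mean(axis=0)
    direction = np.array([1.0, 0.3])
    probs = [typicality(model, centroid + t * direction, "a").probability
             for t in [0.0, 0.5, 1.0, 2.0, 4.0]]
    assert all(p1 > p2 for p1, p2 in zip(probs, probs[1:]))


def test_typicality_unknown_group_and_f_variant():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(30, 2))
    labels = ["a"] * 15 + ["b"] * 15
    model = cva(X, labels)
    with pytest.raises(ValueError, match="unknown group"):
        typicality(model, X[0], "zzz")
    res = typicality(model, X[0], "a", variant="f")
    assert res.variant == "f"
    assert 0.0 <= res.probability <= 1.0


def test_typicality_in_group_probabilities_uniform():
    """Probability-integral transform: in-group specimens have uniform
    typicality probabilities (KS p > 0.01 over 2000 draws)."""
    rng = np.random.default_rng(15)
    n_fit = 1000
    X = np.vstack([rng.normal(0, 1, (n_fit, 3)), rng.normal([4, 0, 0], 1, (n_fit, 3))])
    model = cva(X, ["a"] * n_fit + ["b"] * n_fit)
    fresh = rng.normal(0, 1, (2000, 3))
    probs = [typicality(model, f, "a").probability for f in fresh]
    assert stats.kstest(probs, "uniform").pvalue > 0.01


def test_loo_identical_groups_near_chance():
    rng = np.random.default_rng(16)
    X = rng.normal(size=(40, 3))
    labels = ["a"] * 20 + ["b"] * 20
    acc = loo_classification(X, labels)["overall_accuracy"]
    # binomial 95% band around 0.5 at n = 40
    assert 0.30 <= acc <= 0.70


def test_loo_forced_separation_perfect():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(30, 3))
    X[15:] += [10, 0, 0]
    res = loo_classification(X, ["a"] * 15 + ["b"] * 15)
    assert res["overall_accuracy"] == 1.0
    assert res["confusion"].loc["a", "a"] == 15


def test_loo_rejects_duplicate_ids_and_tiny_groups():
    rng = np.random.default_rng(18)
    X = rng.normal(size=(8, 2))
    labels = ["a"] * 4 + ["b"] * 4
    with pytest.raises(ValueError, match="duplicate"):
        loo_classification(X, labels, ids=["s1", "s1"] + [f"s{i}" for i in range(2, 8)])
    with pytest.raises(ValueError, match="fewer than 3"):
        loo_classification(X[:5], ["a"] * 3 + ["b"] * 2)
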