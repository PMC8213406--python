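"""Feature-table statistics against explicit oracles."""

import numpy as np
import pandas as pd
import pytest

from vocalvae import stats


# --------------------------------------------------------------------- MMD
def _mmd2_double_loop(X, Y, sigma, biased=True):
    """Explicit double-loop kernel-sum oracle."""
    k = lambda a, b: np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))
    n, m = len(X), len(Y)
    kxx = sum(k(X[i], X[j]) for i in range(n) for j in range(n))
    kyy = sum(k(Y[i], Y[j]) for i in range(m) for j in range(m))
    kxy = sum(k(X[i], Y[j]) for i in range(n) for j in range(m))
    if biased:
        return kxx / n**2 + kyy / m**2 - 2 * kxy / (n * m)
    kxx -= sum(k(X[i], X[i]) for i in range(n))
    kyy -= sum(k(Y[i], Y[i]) for i in range(m))
    return kxx / (n * (n - 1)) + kyy / (m * (m - 1)) - 2 * kxy / (n * m)


@pytest.mark.parametrize("estimator", ["biased", "unbiased"])
def test_mmd_matches_double_loop_oracle(estimator):
    rng = np.random.default_rng(0)
    X, Y = rng.normal(0, 1, (50, 3)), rng.normal(0.3, 1.2, (50, 3))
    sigma = 1.7
    ours = stats.mmd2(X, Y, stats.MMDConfig(estimator=estimator), sigma=sigma)
    oracle = _mmd2_double_loop(X, Y, sigma, biased=(estimator == "biased"))
    assert ours == pytest.approx(oracle, abs=1e-10)


def test_mmd_identical_samples_zero():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (30, 4))
    assert stats.mmd2(X, X.copy()) == pytest.approx(0.0, abs=1e-12)


def test_mmd_two_point_worked_case():
    """||x-y|| = sigma gives biased MMD^2 = 2 - 2 e^{-1/2} for two singletons."""
    x, y = np.zeros((2, 3)), np.zeros((2, 3))
    y[:, 0] = 1.0  # distance 1 between the two clouds' points
    val = stats.mmd2(x, y, sigma=1.0)
    assert val == pytest.approx(2 - 2 * np.exp(-0.5), abs=1e-12)


def test_mmd_gaussian_mean_shift_closed_form():
    """Estimator agrees with the Gaussian-integral population MMD^2."""
    d, delta, sigma, n = 4, 0.8, 2.0, 400
    m = np.zeros(d)
    m2 = np.full(d, delta / np.sqrt(d))

    def pop_term(a, b):
        # E exp(-||x-y||^2 / (2 sigma^2)), x~N(a,I), y~N(b,I) independent
        s2 = sigma**2
        return (s2 / (s2 + 2)) ** (d / 2) * np.exp(
            -np.sum((a - b) ** 2) / (2 * (s2 + 2))
        )

    pop = pop_term(m, m) + pop_term(m2, m2) - 2 * pop_term(m, m2)
    reps = []
    for s in range(12):
        rng = np.random.default_rng(100 + s)
        X = rng.normal(m, 1.0, (n, d))
        Y = rng.normal(m2, 1.0, (n, d))
        reps.append(stats.mmd2(X, Y, stats.MMDConfig(estimator="unbiased"),
                               sigma=sigma))
    sem = np.std(reps, ddof=1) / np.sqrt(len(reps))
    assert abs(np.mean(reps) - pop) < 3 * sem + 1e-4


def test_median_bandwidth():
    two = np.array([[0.0, 0.0], [2.0, 0.0]])
    assert stats.median_bandwidth(two) == pytest.approx(2.0)
    assert stats.median_bandwidth(two, fraction=0.25) == pytest.approx(0.5)
    rng = np.random.default_rng(2)
    Z = rng.normal(0, 1, (40, 3))
    c = 3.7
    assert stats.median_bandwidth(Z * c) == pytest.approx(c * stats.median_bandwidth(Z))
    with pytest.raises(ValueError, match="identical"):
        stats.median_bandwidth(np.ones((5, 2)))


def test_mmd_matrix_structure():
    rng = np.random.default_rng(3)
    A = rng.normal(0, 1, (40, 3))
    B = rng.normal(0.1, 1, (40, 3))
    C = rng.normal(3.0, 1, (40, 3))
    M = stats.mmd_matrix({"a1": A, "a2": B, "far": C})
    assert np.allclose(M, M.T, atol=1e-12)
    assert np.allclose(np.diag(M), 0.0)
    assert M.loc["a1", "a2"] < M.loc["a1", "far"]
    assert M.loc["a1", "a2"] < M.loc["a2", "far"]
    dup = stats.mmd_matrix([A, A])
    assert dup.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="degenerate"):
        stats.mmd_matrix({"ok": A, "bad": A[:1]})


# ------------------------------------------------------- variability index
def test_variability_index_enumerable_cases():
    assert stats.variability_index(np.array([[0.0], [1.0], [2.0]])) == 1.0
    same = np.ones((5, 3))
    assert stats.variability_index(same) == 0.0
    assert stats.variability_index_fast(same) == 0.0


def test_variability_index_rotation_invariant():
    rng = np.random.default_rng(4)
    Z = rng.normal(0, 1, (60, 3))
    q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
    assert stats.variability_index(Z @ q) == pytest.approx(
        stats.variability_index(Z), rel=1e-10
    )


def test_fast_vi_close_to_exact_on_gaussian():
    rng = np.random.default_rng(5)
    Z = rng.normal(0, 1, (1000, 5))
    exact = stats.variability_index(Z)
    fast = stats.variability_index_fast(Z)
    assert abs(fast - exact) / exact < 0.10


def test_fast_vi_symmetric_set_center():
    Z = np.array([[1.0, 0], [-1, 0], [0, 2], [0, -2]])
    # coordinate-wise median is the origin
    assert stats.variability_index_fast(Z) == pytest.approx(
        np.median(np.sum(Z**2, axis=1))
    )


def test_variability_reduction_properties():
    rng = np.random.default_rng(6)
    Z = rng.normal(0, 1, (100, 4))
    assert stats.variability_reduction(Z, Z.copy()) == pytest.approx(0.0, abs=1e-12)
    c = 2.5
    r1 = stats.variability_reduction(0.5 * Z, Z)
    r2 = stats.variability_reduction(0.5 * c * Z, c * Z)
    assert r1 == pytest.approx(r2, rel=1e-10)
    assert r1 > 0
    with pytest.raises(ValueError, match="zero"):
        stats.variability_reduction(Z, np.ones((10, 4)))


# -------------------------------------------------------- cross-prediction
def test_cross_predict_identity_noise_and_asymmetry():
    rng = np.random.default_rng(7)
    n = 2000
    t = rng.uniform(0, 1, n)
    manifold = np.column_stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
    manifold += 0.01 * rng.normal(size=manifold.shape)
    same = stats.cross_predict(manifold, manifold.copy(), seed=0)
    assert same["a_to_b"] > 0.95 and same["b_to_a"] > 0.95

    noise = rng.normal(0, 1, (n, 2))
    null = stats.cross_predict(manifold, noise, seed=0)
    assert abs(null["a_to_b"]) < 0.05

    # nested information: A = (f1, f2, f3), B = (f1) only
    F = rng.normal(0, 1, (n, 3))
    res = stats.cross_predict(F, F[:, :1], seed=0)
    assert res["a_to_b"] > 0.5
    assert res["b_to_a"] < 0.5 * res["a_to_b"]


def test_cross_predict_misaligned_rows_error():
    with pytest.raises(ValueError, match="misaligned"):
        stats.cross_predict(np.zeros((10, 2)), np.zeros((9, 2)))


# --------------------------------------------- effective dimensionality
def test_effdim_curve_iid_and_duplicated_column():
    rng = np.random.default_rng(8)
    d, n = 8, 5000
    Z = rng.normal(0, 1, (n, d))
    curve = stats.effective_dimensionality_curve(Z)
    assert len(curve) == d
    assert (np.diff(curve) >= -1e-12).all()
    assert curve[-1] == pytest.approx(1.0)
    np.testing.assert_allclose(curve, np.arange(1, d + 1) / d, atol=0.03)

    dup = Z.copy()
    dup[:, 1] = dup[:, 0]  # one perfectly duplicated pair among d columns
    curve_dup = stats.effective_dimensionality_curve(dup)
    assert curve_dup[0] == pytest.approx(2 / d, abs=0.02)


def test_effdim_zero_variance_column_dropped():
    rng = np.random.default_rng(9)
    Z = np.column_stack([rng.normal(0, 1, (50, 3)), np.zeros(50)])
    with pytest.warns(UserWarning, match="zero-variance"):
        curve = stats.effective_dimensionality_curve(Z)
    assert len(curve) == 3


# ------------------------------------------------------- nearest neighbors
def test_nearest_neighbors_oracle_and_contract():
    rng = np.random.default_rng(10)
    Z = pd.DataFrame(rng.normal(0, 1, (100, 4)))
    q = rng.normal(0, 1, 4)
    got = stats.nearest_neighbors(q, Z, 10)
    d = np.linalg.norm(Z.to_numpy() - q, axis=1)
    oracle = [i for i in np.argsort(d, kind="stable")[:10]]
    assert got == oracle
    assert stats.nearest_neighbors(Z.iloc[3].to_numpy(), Z, 1) == [3]
    assert sorted(stats.nearest_neighbors(q, Z, 100)) == list(range(100))
    with pytest.raises(ValueError, match="exceeds"):
        stats.nearest_neighbors(q, Z, 101)


# --------------------------------------------------- clustering evaluation
def test_cluster_eval_separated_blobs():
    rng = np.random.default_rng(11)
    centers = np.eye(4)[:, :3] * 12
    Z = np.vstack([rng.normal(c, 1.0, (60, 3)) for c in centers])
    res = stats.cluster_eval(Z, k=4, folds=10, seed=0)
    assert (res.differences["silhouette"] > 0).all()
    assert (res.differences["calinski_harabasz"] > 0).all()
    assert (res.differences["davies_bouldin"] > 0).all()  # sign-flipped


def test_cluster_eval_null_on_null():
    rng = np.random.default_rng(12)
    Z = rng.normal(0, 1, (600, 4))
    res = stats.cluster_eval(Z, k=6, folds=10, seed=1)
    assert abs(res.differences["silhouette"].mean()) < 0.05


def test_cluster_eval_k_sweep_supported():
    rng = np.random.default_rng(13)
    Z = np.vstack([rng.normal(c, 0.5, (80, 2)) for c in ([0, 0], [6, 0], [0, 6])])
    for k in (2, 6, 12):
        res = stats.cluster_eval(Z, k=k, folds=2, seed=0)
        assert len(res.differences) == 2


def test_gmm_label_consistency_bounds():
    rng = np.random.default_rng(14)
    blobs = np.vstack([rng.normal(c, 0.3, (80, 2)) for c in ([0, 0], [8, 0], [0, 8])])
    assert stats.gmm_label_consistency(blobs, k=3, seed=0) > 0.95
    assert stats.gmm_label_consistency(blobs, k=1, seed=0) == 1.0
    single = rng.normal(0, 1, (600, 4))
    assert (
        stats.gmm_label_consistency(single, k=6, seed=0)
        < stats.gmm_label_consistency(blobs, k=3, seed=0)
    )


def test_feature_table_roundtrip(tmp_path):
    df = pd.DataFrame(
        np.random.default_rng(15).normal(0, 1, (6, 3)),
        columns=["f1", "f2", "f3"],
        index=[f"syl{i}" for i in range(6)],
    )
    path = tmp_path / "feat.csv"
    stats.write_feature_table(df, path)
    back = stats.read_feature_table(path)
    pd.testing.assert_frame_equal(df, back)
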