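import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eoscluster import fcm_fit, objective, update_centroids, update_memberships


def naive_objective(X, V, U, m):
    """Independent brute-force double sum for the FCM objective."""
    total = 0.0
    for i in range(X.shape[0]):
        for j in range(V.shape[0]):
            total += U[i, j] ** m * np.sum((X[i] - V[j]) ** 2)
    return total


def lloyd_kmeans(X, centers, max_iter=200):
    """Brute-force Lloyd iteration from given starting centers."""
    V = np.array(centers, dtype=float)
    for _ in range(max_iter):
        d = ((X[:, None, :] - V[None]) ** 2).sum(-1)
        assign = d.argmin(axis=1)
        V_new = np.array([X[assign == j].mean(axis=0) for j in range(len(V))])
        if np.allclose(V_new, V):
            break
        V = V_new
    return assign


class TestUpdateMemberships:
    def test_point_on_centroid_gets_full_membership(self):
        X = np.array([[1.0, 2.0]])
        V = np.array([[1.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        U = update_memberships(X, V, m=2.0)
        np.testing.assert_allclose(U, [[1.0, 0.0, 0.0]])

    def test_equidistant_point_splits_evenly(self):
        X = np.array([[0.0, 0.0]])
        V = np.array([[-1.0, 0.0], [1.0, 0.0]])
        U = update_memberships(X, V, m=2.0)
        np.testing.assert_allclose(U, [[0.5, 0.5]], atol=1e-12)

    def test_hand_derived_distance_ratio(self):
        # distances (1, 3), m = 2: u1 = 1/(1 + (1/3)^2) = 0.9
        X = np.array([[0.0]])
        V = np.array([[1.0], [-3.0]])
        U = update_memberships(X, V, m=2.0)
        np.testing.assert_allclose(U, [[0.9, 0.1]], atol=1e-12)

    def test_coincident_centroids_split_equally(self):
        X = np.array([[2.0, 2.0]])
        V = np.array([[2.0, 2.0], [2.0, 2.0], [7.0, 7.0]])
        U = update_memberships(X, V, m=2.0)
        np.testing.assert_allclose(U, [[0.5, 0.5, 0.0]])

    def test_small_fuzzifier_is_numerically_stable(self, rng):
        X = rng.normal(size=(50, 6))
        V = rng.normal(size=(4, 6))
        U = update_memberships(X, V, m=1.05)
        assert np.isfinite(U).all()
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-9)

    @given(seed=st.integers(0, 10_000), m=st.floats(1.2, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one(self, seed, m):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 3))
        V = rng.normal(size=(3, 3))
        U = update_memberships(X, V, m=m)
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-9)
        assert ((U >= 0) & (U <= 1)).all()


class TestUpdateCentroids:
    def test_crisp_memberships_reduce_to_group_means(self, rng):
        X = rng.normal(size=(10, 2))
        U = np.zeros((10, 2))
        U[:5, 0] = 1.0
        U[5:, 1] = 1.0
        for m in (1.5, 2.0, 3.0):
            V = update_centroids(X, U, m)
            np.testing.assert_allclose(V[0], X[:5].mean(axis=0))
            np.testing.assert_allclose(V[1], X[5:].mean(axis=0))

    def test_uniform_memberships_collapse_to_grand_mean(self):
        X = np.array([[0.0], [4.0]])
        U = np.full((2, 2), 0.5)
        V = update_centroids(X, U, m=2.0)
        np.testing.assert_allclose(V, [[2.0], [2.0]])

    def test_matches_weighted_mean_oracle(self, rng):
        X = rng.normal(size=(15, 4))
        U = rng.dirichlet(np.ones(3), size=15)
        m = 2.0
        V = update_centroids(X, U, m)
        W = U**m
        for j in range(3):
            expected = (W[:, j : j + 1] * X).sum(axis=0) / W[:, j].sum()
            np.testing.assert_allclose(V[j], expected, atol=1e-12)

    def test_centroids_in_convex_hull_bounds(self, rng):
        X = rng.uniform(-3, 3, size=(30, 2))
        U = rng.dirichlet(np.ones(4), size=30)
        V = update_centroids(X, U, m=2.0)
        assert (V >= X.min(axis=0) - 1e-12).all()
        assert (V <= X.max(axis=0) + 1e-12).all()

    def test_empty_cluster_rescued(self, caplog):
        X = np.arange(8, dtype=float).reshape(4, 2)
        U = np.zeros((4, 3))
        U[:, 0] = 1.0  # cluster 1 and 2 have zero weight
        with caplog.at_level("WARNING"):
            V = update_centroids(X, U, m=2.0)
        assert np.isfinite(V).all()
        assert "re-seeded" in caplog.text


class TestObjective:
    def test_zero_iff_points_on_their_centroids(self):
        X = np.array([[0.0, 0.0], [3.0, 3.0]])
        V = X.copy()
        U = np.eye(2)
        assert objective(X, V, U, m=2.0) == 0.0

    def test_single_point_hand_value(self):
        # membership 1, m = 2, distance 2: J = 1^2 * 2^2 = 4
        X = np.array([[2.0]])
        V = np.array([[0.0]])
        U = np.array([[1.0]])
        assert objective(X, V, U, m=2.0) == pytest.approx(4.0)

    def test_matches_naive_double_sum(self, rng):
        for _ in range(5):
            X = rng.normal(size=(20, 6))
            V = rng.normal(size=(3, 6))
            U = rng.dirichlet(np.ones(3), size=20)
            m = float(rng.uniform(1.3, 3.0))
            assert objective(X, V, U, m) == pytest.approx(
                naive_objective(X, V, U, m), rel=1e-12
            )


class TestFcmFit:
    def test_recovers_separated_cloud_centers(self, two_clouds):
        X, labels = two_clouds
        model = fcm_fit(X, k=2, seed=0)
        # match fitted centroids to generative centers
        true_centers = np.array([X[labels == 0].mean(0), X[labels == 1].mean(0)])
        d = ((model.centroids_std[:, None] - true_centers[None]) ** 2).sum(-1)
        order = d.argmin(axis=1)
        assert sorted(order) == [0, 1]
        for j in range(2):
            assert np.linalg.norm(model.centroids_std[j] - true_centers[order[j]]) < 0.2
        assert model.memberships.max(axis=1).mean() > 0.95

    def test_duplicated_data_leaves_centroids_unchanged(self, two_clouds):
        X, _ = two_clouds
        m1 = fcm_fit(X, k=2, seed=3)
        m2 = fcm_fit(np.vstack([X, X]), k=2, seed=3)
        d = ((m1.centroids_std[:, None] - m2.centroids_std[None]) ** 2).sum(-1)
        assert np.sqrt(d.min(axis=1)).max() < 1e-3

    def test_same_seed_bit_identical_trace(self, two_clouds):
        X, _ = two_clouds
        t1 = fcm_fit(X, k=2, seed=7).objective_trace
        t2 = fcm_fit(X, k=2, seed=7).objective_trace
        assert t1 == t2

    def test_objective_trace_never_increases(self, rng):
        for _ in range(3):
            X = rng.normal(size=(60, 4))
            model = fcm_fit(X, k=3, seed=1, n_starts=3)
            trace = np.asarray(model.objective_trace)
            assert (np.diff(trace) <= 1e-10).all()

    def test_row_stochastic_result(self, two_clouds):
        X, _ = two_clouds
        model = fcm_fit(X, k=3, seed=5)
        np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_hard_limit_matches_lloyd_kmeans(self, two_clouds):
        X, labels = two_clouds
        model = fcm_fit(X, k=2, m=1.05, seed=2)
        fcm_assign = model.memberships.argmax(axis=1)
        km_assign = lloyd_kmeans(X, [X[labels == 0].mean(0), X[labels == 1].mean(0)])
        # compare up to label permutation
        agree = (fcm_assign == km_assign).mean()
        assert max(agree, 1 - agree) == 1.0

    def test_permutation_invariance(self, two_clouds, rng):
        X, _ = two_clouds
        perm = rng.permutation(len(X))
        m1 = fcm_fit(X, k=2, seed=4)
        m2 = fcm_fit(X[perm], k=2, seed=4)
        # centroids agree up to cluster relabeling
        d = ((m1.centroids_std[:, None] - m2.centroids_std[None]) ** 2).sum(-1)
        order = d.argmin(axis=1)
        assert sorted(order.tolist()) == [0, 1]
        np.testing.assert_allclose(
            m1.memberships, m2.memberships[np.argsort(perm)][:, order], atol=1e-4
        )

    def test_rejects_bad_inputs(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            fcm_fit(X, k=6)
        with pytest.raises(ValueError):
            fcm_fit(X, k=1)
        with pytest.raises(ValueError):
            fcm_fit(X, k=2, m=1.0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fcm_fit(X, k=2)

    def test_model_json_round_trip(self, two_clouds, tmp_path):
        from eoscluster import ClusterModel

        X, _ = two_clouds
        model = fcm_fit(X, k=2, seed=9)
        path = tmp_path / "model.json"
        model.save_json(path)
        back = ClusterModel.load_json(path)
        np.testing.assert_allclose(back.centroids_std, model.centroids_std)
        assert back.k == model.k
        assert back.fuzzifier_m == model.fuzzifier_m
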