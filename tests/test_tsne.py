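import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import knn_label_agreement, random_simplex
from qdl.synth import generate_cluster_features, generate_dirichlet_clusters
from qdl.tsne import (
    EmbedConfig,
    bhattacharyya_distance,
    bregman_divergence,
    conditional_affinities,
    joint_affinities,
    pairwise_distances,
    trustworthiness,
    tsne_embed,
    tsne_gradient,
)


class TestBhattacharyyaDistance:
    def test_identical_is_zero(self):
        assert bhattacharyya_distance([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_disjoint_support_is_inf(self):
        assert bhattacharyya_distance([1.0, 0.0], [0.0, 1.0]) == np.inf

    def test_hand_value(self):
        # -ln(sqrt(0.45) + sqrt(0.05)) evaluated independently
        expected = -np.log(np.sqrt(0.5 * 0.9) + np.sqrt(0.5 * 0.1))
        got = bhattacharyya_distance([0.5, 0.5], [0.9, 0.1])
        assert abs(got - expected) < 1e-12
        assert abs(got - 0.11157) < 5e-5

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bhattacharyya_distance([0.5, 0.5], [0.2, 0.3, 0.5])

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            bhattacharyya_distance([0.7, 0.7], [0.5, 0.5])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    def test_properties_random_pairs(self, seed, dim):
        rng = np.random.default_rng(seed)
        p = random_simplex(rng, dim)
        q = random_simplex(rng, dim)
        d_pq = bhattacharyya_distance(p, q)
        assert d_pq >= 0.0
        assert d_pq == bhattacharyya_distance(q, p)
        assert bhattacharyya_distance(p, p) < 1e-12


class TestPairwiseDistances:
    def test_symmetry_and_diagonal(self, rng):
        X = rng.standard_normal((10, 4))
        D = pairwise_distances(X)
        np.testing.assert_array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_duplicate_rows_zero(self, rng):
        X = rng.random((5, 3))
        X[3] = X[1]
        D = pairwise_distances(X)
        assert D[1, 3] == 0.0

    def test_matches_scalar_loop_oracle(self, rng):
        X = np.vstack([random_simplex(rng, 6) for _ in range(4)])
        D = pairwise_distances(X, metric="bhattacharyya")
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                assert abs(D[i, j] - bhattacharyya_distance(X[i], X[j])) < 1e-12

    def test_rejects_non_simplex_rows(self, rng):
        with pytest.raises(ValueError):
            pairwise_distances(rng.standard_normal((4, 4)), metric="bhattacharyya")


def _row_perplexity_bits(row: np.ndarray) -> float:
    nz = row[row > 0]
    return float(2.0 ** (-(nz * np.log2(nz)).sum()))


class TestConditionalAffinities:
    def test_equidistant_rows_uniform(self):
        D = np.ones((6, 6)) - np.eye(6)
        P = conditional_affinities(D, 3.0)
        np.testing.assert_allclose(P[P > 0], 1 / 5, atol=1e-12)
        assert abs(_row_perplexity_bits(P[0]) - 5.0) < 1e-9

    def test_rows_sum_to_one(self, rng):
        X = rng.standard_normal((20, 5))
        P = conditional_affinities(pairwise_distances(X), 7.0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diag(P) == 0)

    def test_achieved_perplexity_fixed_instance(self):
        rng = np.random.default_rng(99)
        D = pairwise_distances(rng.standard_normal((5, 3)))
        P = conditional_affinities(D, 2.0)
        for row in P:
            assert 1.9998 <= _row_perplexity_bits(row) <= 2.0002

    def test_achieved_perplexity_random_instances(self, rng):
        for target in (5.0, 10.0, 30.0):
            D = pairwise_distances(rng.standard_normal((50, 8)))
            P = conditional_affinities(D, target)
            for row in P:
                assert abs(_row_perplexity_bits(row) - target) <= 1e-4 * target

    def test_infinite_distances_capped(self):
        D = np.array([[0.0, 1.0, np.inf], [1.0, 0.0, 2.0], [np.inf, 2.0, 0.0]])
        P = conditional_affinities(D, 1.5)
        assert np.all(np.isfinite(P))

    def test_perplexity_bounds(self):
        with pytest.raises(ValueError):
            conditional_affinities(np.zeros((4, 4)), 4.0)


class TestBregmanDivergence:
    def test_zero_at_equal_inputs(self, rng):
        P = rng.random((4, 4))
        for gen in ("generalized_kl", "squared_euclidean"):
            assert bregman_divergence(P, P, gen) == 0.0

    def test_squared_euclidean_hand_value(self):
        assert bregman_divergence([1.0, 0.0], [0.0, 1.0], "squared_euclidean") == 1.0

    def test_generalized_kl_hand_value(self):
        # 1*log(1/0.5) - 1 + 1 = ln 2, with 0 log 0 = 0
        got = bregman_divergence([1.0, 0.0], [0.5, 0.5], "generalized_kl")
        assert abs(got - np.log(2)) < 1e-12

    def test_zero_q_facing_positive_p_is_inf(self):
        assert bregman_divergence([0.5, 0.5], [1.0, 0.0], "generalized_kl") == np.inf

    def test_equals_textbook_kl_on_normalized(self, rng):
        from scipy.special import rel_entr

        for _ in range(20):
            p = random_simplex(rng, 8) + 1e-9
            q = random_simplex(rng, 8) + 1e-9
            p, q = p / p.sum(), q / q.sum()
            assert abs(bregman_divergence(p, q, "generalized_kl") - rel_entr(p, q).sum()) < 1e-12

    def test_nonnegative(self, rng):
        for _ in range(50):
            P = rng.random((3, 5))
            Q = rng.random((3, 5)) + 0.01
            for gen in ("generalized_kl", "squared_euclidean"):
                assert bregman_divergence(P, Q, gen) >= 0.0


class TestGradient:
    @pytest.mark.parametrize("kernel", ["student_t", "simplex_bhattacharyya"])
    @pytest.mark.parametrize("divergence", ["kl", "squared_euclidean"])
    def test_matches_central_differences(self, kernel, divergence):
        rng = np.random.default_rng(17)
        cfg = EmbedConfig(perplexity=3.0, low_dim_kernel=kernel, divergence=divergence)
        X = rng.standard_normal((10, 4))
        P = joint_affinities(conditional_affinities(pairwise_distances(X), 3.0))
        Y = rng.standard_normal((10, 2)) * 0.5
        _, grad = tsne_gradient(P, Y, cfg)
        eps = 1e-6
        numeric = np.zeros_like(Y)
        for i in range(Y.shape[0]):
            for k in range(Y.shape[1]):
                Yp, Ym = Y.copy(), Y.copy()
                Yp[i, k] += eps
                Ym[i, k] -= eps
                numeric[i, k] = (tsne_gradient(P, Yp, cfg)[0] - tsne_gradient(P, Ym, cfg)[0]) / (2 * eps)
        scale = max(np.abs(numeric).max(), 1e-12)
        assert np.abs(grad - numeric).max() / scale < 1e-5


class TestEmbed:
    def test_seeded_determinism(self):
        lf = generate_cluster_features(8, 2, 5, 5.0, seed=0)
        cfg = EmbedConfig(perplexity=4.0, max_iter=60, seed=42)
        Y1, t1 = tsne_embed(lf.matrix, cfg)
        Y2, t2 = tsne_embed(lf.matrix, cfg)
        np.testing.assert_array_equal(Y1, Y2)
        assert t1 == t2

    def test_baseline_separates_clusters(self):
        lf = generate_cluster_features(30, 3, 10, 10.0, seed=1)
        cfg = EmbedConfig(perplexity=10.0, max_iter=400, seed=1)
        Y, _ = tsne_embed(lf.matrix, cfg)
        assert knn_label_agreement(Y, lf.labels) >= 0.9

    def test_modified_mode_separates_dirichlet_families(self):
        lf = generate_dirichlet_clusters(30, 3, 16, 60.0, seed=2)
        cfg = EmbedConfig(
            perplexity=10.0, max_iter=400, seed=2, input_metric="bhattacharyya", divergence="generalized_kl"
        )
        Y, _ = tsne_embed(lf.matrix, cfg)
        assert knn_label_agreement(Y, lf.labels) >= 0.85

    def test_simplex_kernel_runs(self):
        lf = generate_dirichlet_clusters(10, 2, 8, 50.0, seed=3)
        cfg = EmbedConfig(
            perplexity=5.0,
            max_iter=50,
            learning_rate=1.0,
            seed=3,
            input_metric="bhattacharyya",
            low_dim_kernel="simplex_bhattacharyya",
            divergence="generalized_kl",
        )
        Y, trace = tsne_embed(lf.matrix, cfg)
        assert np.all(np.isfinite(Y)) and len(trace) == 50

    def test_cost_trace_nonincreasing_without_exaggeration(self):
        lf = generate_cluster_features(15, 3, 8, 6.0, seed=5)
        cfg = EmbedConfig(
            perplexity=8.0,
            max_iter=300,
            learning_rate=5.0,
            early_exaggeration=1.0,
            early_exaggeration_iters=0,
            seed=5,
        )
        _, trace = tsne_embed(lf.matrix, cfg)
        tail = np.asarray(trace[50:])
        increases = (np.diff(tail) > 1e-12).sum()
        assert increases <= max(1, int(0.01 * len(tail)))

    def test_pca_init(self):
        lf = generate_cluster_features(10, 2, 6, 6.0, seed=6)
        cfg = EmbedConfig(perplexity=4.0, max_iter=30, seed=6, init="pca")
        Y, _ = tsne_embed(lf.matrix, cfg)
        assert Y.shape == (20, 2)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            tsne_embed(np.zeros((2, 3)), EmbedConfig(perplexity=1.5))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            EmbedConfig(perplexity=0.5)
        with pytest.raises(ValueError):
            EmbedConfig(divergence="hellinger")


class TestTrustworthiness:
    def test_rigid_rotation_is_perfect(self, rng):
        X = rng.standard_normal((40, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        D = pairwise_distances(X)
        assert trustworthiness(D, X @ R.T, k=5) == pytest.approx(1.0)

    def test_random_embedding_worse_than_optimized(self):
        lf = generate_cluster_features(34, 3, 10, 8.0, seed=7)
        D = pairwise_distances(lf.matrix)
        cfg = EmbedConfig(perplexity=10.0, max_iter=300, seed=7)
        Y_opt, _ = tsne_embed(lf.matrix, cfg)
        Y_rand = np.random.default_rng(7).standard_normal(Y_opt.shape)
        assert trustworthiness(D, Y_opt, k=5) > trustworthiness(D, Y_rand, k=5)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.manifold import trustworthiness as sk_trust

        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 2))
        D = pairwise_distances(X)
        ours = trustworthiness(D, Y, k=5)
        theirs = sk_trust(X, Y, n_neighbors=5)
        assert abs(ours - theirs) < 1e-9

    def test_range_property(self, rng):
        for _ in range(5):
            X = rng.standard_normal((20, 4))
            Y = rng.standard_normal((20, 2))
            val = trustworthiness(pairwise_distances(X), Y, k=4)
            assert 0.0 <= val <= 1.0

    def test_k_out_of_range(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            trustworthiness(pairwise_distances(X), X[:, :2], k=5)
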