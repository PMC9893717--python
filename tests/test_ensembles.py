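import numpy as np
import pytest

from ensemblepipe import (
    AdjacencyGraph,
    EmbeddingParams,
    EnsembleAssignment,
    EnsembleDetector,
    Raster,
    correlation_distance,
    detect_communities,
    fuzzy_knn_graph,
    generate_raster,
    modularity_matrix,
    partition_modularity,
    preset,
    sort_raster,
)
from ensemblepipe.synth import SynthConfig, even_membership

from _oracles import exhaustive_modularity_partition, small_graph_suite


class TestCorrelationDistance:
    def test_identical_rows_have_zero_distance(self):
        d = correlation_distance(np.array([[1, 0, 1, 0], [1, 0, 1, 0]]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_have_distance_two(self):
        d = correlation_distance(np.array([[1, 0, 1, 0], [0, 1, 0, 1]]))
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_uncorrelated_rows_have_distance_one(self):
        d = correlation_distance(np.array([[1, 1, 0, 0], [1, 0, 1, 0]]))
        assert d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rows_flagged_as_nan_with_warning(self):
        mat = np.array([[1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 0, 0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            d = correlation_distance(mat)
        assert np.isnan(d[1]).all() and np.isnan(d[:, 1]).all()
        assert np.isfinite(d[0, 2])


class TestFuzzyKnnGraph:
    def test_nearest_neighbor_weight_is_one_after_union(self):
        # the directed weight to the nearest neighbor is exp(0)=1, and the
        # probabilistic union keeps any 1 at 1
        rng = np.random.default_rng(0)
        pts = rng.random((8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        g = fuzzy_knn_graph(d, EmbeddingParams(n_neighbors=3))
        for i in range(8):
            nn = np.argsort(np.where(np.arange(8) == i, np.inf, d[i]))[0]
            assert g.weights[i, nn] == pytest.approx(1.0, abs=1e-9)

    def test_three_equidistant_points_fully_connected_equal_weights(self):
        d = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        g = fuzzy_knn_graph(d, EmbeddingParams(n_neighbors=2))
        off = g.weights[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        assert (off > 0).all()

    def test_too_many_neighbors_errors(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="n_neighbors"):
            fuzzy_knn_graph(d, EmbeddingParams(n_neighbors=3))

    def test_nan_distances_rejected(self):
        d = np.full((4, 4), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            fuzzy_knn_graph(d, EmbeddingParams(n_neighbors=2))

    def test_output_is_valid_adjacency_graph(self):
        rng = np.random.default_rng(1)
        pts = rng.random((12, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        g = fuzzy_knn_graph(d, EmbeddingParams(n_neighbors=4))
        assert np.allclose(g.weights, g.weights.T)
        assert g.weights.min() >= 0 and g.weights.max() <= 1
        assert np.all(np.diag(g.weights) == 0)


class TestModularityMatrix:
    def test_full_matrix_rows_sum_to_zero(self):
        suite = small_graph_suite(seed=5)
        for w in suite.values():
            b = modularity_matrix(AdjacencyGraph(w)).entries
            assert np.abs(b.sum(axis=1)).max() < 1e-9

    def test_group_restriction_to_all_nodes_also_sums_to_zero(self):
        w = small_graph_suite(seed=5)["two_4cliques"]
        b = modularity_matrix(AdjacencyGraph(w), group=range(8)).entries
        assert np.abs(b.sum(axis=1)).max() < 1e-9

    def test_two_disconnected_triangles_split_has_q_half(self):
        w = small_graph_suite()["two_triangles"]
        q = partition_modularity(AdjacencyGraph(w), np.array([0, 0, 0, 1, 1, 1]))
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="no edges"):
            modularity_matrix(AdjacencyGraph(np.zeros((3, 3))))


class TestDetectCommunities:
    def test_two_disconnected_4cliques_recovered_exactly(self):
        w = small_graph_suite()["two_4cliques"]
        a = detect_communities(AdjacencyGraph(w), consensus_runs=5, seed=0)
        assert a.n_ensembles == 2
        labels = a.labels
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        # modularity matches the exhaustive recursive-search oracle
        _, q_star = exhaustive_modularity_partition(w)
        assert a.modularity_q == pytest.approx(q_star, abs=1e-9)

    def test_complete_graph_stays_one_community(self):
        n = 8
        w = np.ones((n, n))
        np.fill_diagonal(w, 0)
        a = detect_communities(AdjacencyGraph(w), consensus_runs=5, seed=0)
        assert a.n_ensembles == 1

    def test_matches_exhaustive_oracle_on_small_graph_suite(self):
        for name, w in small_graph_suite(seed=17).items():
            a = detect_communities(AdjacencyGraph(w), consensus_runs=5, seed=1)
            _, q_star = exhaustive_modularity_partition(w)
            assert a.modularity_q == pytest.approx(q_star, abs=1e-9), name

    def test_labels_equivariant_under_node_permutation(self):
        w = small_graph_suite(seed=3)["planted_0"]
        rng = np.random.default_rng(8)
        perm = rng.permutation(w.shape[0])
        a1 = detect_communities(AdjacencyGraph(w), consensus_runs=5, seed=2)
        a2 = detect_communities(
            AdjacencyGraph(w[np.ix_(perm, perm)]), consensus_runs=5, seed=2
        )
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a1.labels[perm], a2.labels) == 1.0


class TestEnsembleDetector:
    def test_recovers_planted_ensembles_with_high_agreement(self):
        cfg = SynthConfig(
            n_neurons=30, n_frames=1200, fps=4.0, n_ensembles=3,
            membership=even_membership(30, 3), epoch_length=10,
            sequence=(0, 1, 2), p_active_in_epoch=0.95, p_background=0.01,
            seed=4,
        )
        raster, truth = generate_raster(cfg)
        det = EnsembleDetector(n_neighbors=5).fit(raster)
        from sklearn.metrics import adjusted_rand_score

        assert det.n_ensembles_ == 3
        assert adjusted_rand_score(truth.labels, det.labels_) >= 0.9

    def test_silent_neurons_are_excluded_and_labeled_minus_one(self):
        cfg = SynthConfig(
            n_neurons=22, n_frames=800, fps=4.0, n_ensembles=2,
            membership=(tuple(range(10)), tuple(range(10, 20))),
            epoch_length=10, sequence=(0, 1),
            p_active_in_epoch=1.0, p_background=0.0, seed=0,
        )
        raster, _ = generate_raster(cfg)  # neurons 20, 21 stay silent
        det = EnsembleDetector(n_neighbors=5).fit(raster)
        assert set(det.excluded_) == {20, 21}
        assert (det.labels_[[20, 21]] == -1).all()

    def test_sklearn_params_round_trip(self):
        det = EnsembleDetector(n_neighbors=7, consensus_runs=3)
        params = det.get_params()
        assert params["n_neighbors"] == 7
        det2 = EnsembleDetector().set_params(**params)
        assert det2.consensus_runs == 3


class TestSortRaster:
    def _assignment(self, labels):
        return EnsembleAssignment(np.asarray(labels), 0.5)

    def test_first_firing_community_goes_first(self):
        mat = np.zeros((4, 6), dtype=int)
        mat[2, 0] = 1  # community 1 fires first
        mat[0, 3] = 1
        raster = Raster(mat, fps=4.0)
        sorted_r, perm = sort_raster(raster, self._assignment([0, 0, 1, 1]))
        assert perm.tolist() == [2, 3, 0, 1]

    def test_already_sorted_raster_gives_identity_permutation(self):
        mat = np.zeros((4, 6), dtype=int)
        mat[0, 0] = 1
        mat[2, 3] = 1
        raster = Raster(mat, fps=4.0)
        _, perm = sort_raster(raster, self._assignment([0, 0, 1, 1]))
        assert perm.tolist() == [0, 1, 2, 3]

    def test_permutation_recovers_original(self, tiny_raster):
        sorted_r, perm = sort_raster(tiny_raster, self._assignment([1, 0, 0]))
        inverse = np.argsort(perm)
        assert np.array_equal(sorted_r.matrix[inverse], tiny_raster.matrix)

    def test_excluded_neurons_appended_last(self):
        mat = np.eye(3, 5, dtype=int)
        raster = Raster(mat, fps=4.0)
        _, perm = sort_raster(raster, self._assignment([0, -1, 0]))
        assert perm[-1] == 1

    def test_size_mismatch_errors(self, tiny_raster):
        with pytest.raises(ValueError, match="covers"):
            sort_raster(tiny_raster, self._assignment([0, 1]))


@pytest.mark.filterwarnings("ignore")
class TestEmbed:
    def test_shape_and_determinism_and_default_min_dist(self):
        from ensemblepipe import embed

        assert EmbeddingParams().min_dist == 0.1
        rng = np.random.default_rng(0)
        vectors = (rng.random((30, 40)) < 0.3).astype(float)
        params = EmbeddingParams(n_neighbors=5, n_components=2)
        c1 = embed(vectors, params, seed=3)
        c2 = embed(vectors, params, seed=3)
        assert c1.shape == (30, 2)
        assert np.allclose(c1, c2)

    def test_too_few_vectors_error(self):
        from ensemblepipe import embed

        with pytest.raises(ValueError, match="at least"):
            embed(np.zeros((4, 10)), EmbeddingParams(n_neighbors=10))
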