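"""Binarization routes: brain-route thresholding and the LLM-route reduction."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from elscape.preprocess import (
    BinaryStateSeries,
    ClusterAssignment,
    LLMSeriesMeta,
    binarize_brain_route,
    cluster_nodes,
    per_layer_series,
    reduce_and_binarize,
    select_iteration_window,
    znormalize_columns,
)
from elscape.synthetic import emit_continuous_observations, sample_mem_series

from conftest import random_params


def cluster_agreement(labels: np.ndarray, truth: np.ndarray) -> float:
    """Best label-matched agreement via the Hungarian assignment."""
    k = int(truth.max()) + 1
    conf = np.zeros((k, k))
    for lab, t in zip(labels, truth):
        conf[lab - 1, t] += 1
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(labels)


class TestBinarizeBrainRoute:
    def test_row_against_across_node_mean(self):
        row = np.array([[1, 1, 1, 1, 1, 1, 1, 1, 10.0]])
        out = binarize_brain_route(row)
        np.testing.assert_array_equal(out.values[0], [-1] * 8 + [1])

    def test_all_equal_row_is_all_inactive(self):
        # threshold equals every value; the strictly-greater convention gives -1
        out = binarize_brain_route(np.full((3, 9), 2.5))
        assert (out.values == -1).all()

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="9 columns"):
            binarize_brain_route(np.zeros((10, 8)))

    def test_nan_rejected_with_location(self):
        X = np.zeros((4, 9))
        X[2, 5] = np.nan
        with pytest.raises(ValueError, match=r"rows \[2\].*columns \[5\]"):
            binarize_brain_route(X)

    def test_low_noise_recovery_of_latent_states(self):
        latent = sample_mem_series(random_params(0, n=9, scale=0.3), 3000, seed=1)
        obs = emit_continuous_observations(
            latent, nodes_per_cluster=1, noise_sd=0.1, seed=2,
            gain_range=(1.0, 1.0), offset_range=(0.0, 0.0),
        )
        out = binarize_brain_route(obs.data)
        assert np.mean(out.values == latent) > 0.95

    def test_invariant_to_common_positive_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 9))
        a = binarize_brain_route(X)
        b = binarize_brain_route(3.7 * X)
        np.testing.assert_array_equal(a.values, b.values)

    def test_per_node_temporal_mean_mode(self):
        X = np.array([[0.0, 10.0], [2.0, 20.0], [4.0, 30.0]])
        X9 = np.tile(X, (1, 5))[:, :9]
        out = binarize_brain_route(X9, threshold_mode="per_node_temporal_mean")
        np.testing.assert_array_equal(out.values[:, 0], [-1, -1, 1])


class TestSelectIterationWindow:
    def test_default_window_row_count(self):
        X = np.zeros((200_000, 3))
        assert select_iteration_window(X, 10_000, 60_000).shape[0] == 50_000

    def test_identity_and_single_row(self):
        X = np.arange(12.0).reshape(6, 2)
        np.testing.assert_array_equal(select_iteration_window(X, 0, 6), X)
        single = select_iteration_window(X, 3, 4)
        np.testing.assert_array_equal(single, X[3:4])

    def test_out_of_range_window_rejected(self):
        with pytest.raises(ValueError):
            select_iteration_window(np.zeros((10, 2)), 5, 11)
        with pytest.raises(ValueError, match="window"):
            LLMSeriesMeta(n_hidden=4, n_layers=2, n_iterations=10, window_start=8, window_end=8)


class TestClusterNodes:
    def test_recovers_true_column_map(self):
        latent = sample_mem_series(random_params(1, n=9, scale=0.3), 1500, seed=4)
        obs = emit_continuous_observations(latent, nodes_per_cluster=8, noise_sd=0.1, seed=5)
        assignment = cluster_nodes(obs.data, seed=0)
        assert cluster_agreement(assignment.labels, obs.cluster_map) > 0.95

    def test_returns_exactly_nine_clusters(self):
        latent = sample_mem_series(random_params(2, n=9, scale=0.3), 800, seed=6)
        obs = emit_continuous_observations(latent, nodes_per_cluster=3, noise_sd=0.1, seed=7)
        assignment = cluster_nodes(obs.data, seed=1)
        assert assignment.k == 9
        assert len(assignment.counts) == 9

    def test_partition_invariant_to_column_permutation(self):
        latent = sample_mem_series(random_params(3, n=9, scale=0.3), 1000, seed=8)
        obs = emit_continuous_observations(latent, nodes_per_cluster=4, noise_sd=0.05, seed=9)
        perm = np.random.default_rng(10).permutation(obs.data.shape[1])
        a = cluster_nodes(obs.data, seed=2)
        b = cluster_nodes(obs.data[:, perm], seed=2)
        # same partition up to label names: co-membership must match
        co_a = a.labels[:, None] == a.labels[None, :]
        co_b = b.labels[:, None] == b.labels[None, :]
        np.testing.assert_array_equal(co_a[np.ix_(perm, perm)], co_b)

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            cluster_nodes(np.zeros((100, 5)), k=9)

    def test_constant_column_normalized_to_zero(self, caplog):
        X = np.random.default_rng(11).normal(size=(50, 3))
        X[:, 1] = 4.2
        Z = znormalize_columns(X)
        assert (Z[:, 1] == 0).all()


class TestReduceAndBinarize:
    def test_cluster_mean_against_temporal_average(self):
        # cluster 1 mean course (1, 2, 3), temporal average 2 -> (-1, -1, +1)
        X = np.array([[1.0, 9.0], [2.0, 9.0], [3.0, 9.0]])
        clusters = ClusterAssignment(labels=np.array([1, 2]), k=2)
        out = reduce_and_binarize(X, clusters, normalize=False)
        np.testing.assert_array_equal(out.values[:, 0], [-1, -1, 1])

    def test_constant_cluster_all_inactive(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        clusters = ClusterAssignment(labels=np.array([1, 2]), k=2)
        out = reduce_and_binarize(X, clusters, normalize=False)
        assert (out.values[:, 0] == -1).all()

    def test_output_contract(self):
        latent = sample_mem_series(random_params(4, n=9, scale=0.3), 400, seed=12)
        obs = emit_continuous_observations(latent, nodes_per_cluster=3, noise_sd=0.1, seed=13)
        assignment = cluster_nodes(obs.data, seed=3)
        out = reduce_and_binarize(obs.data, assignment)
        assert out.shape == (400, 9)
        assert set(np.unique(out.values)) <= {-1, 1}

    def test_invariant_to_per_cluster_positive_rescaling(self):
        latent = sample_mem_series(random_params(5, n=9, scale=0.3), 300, seed=14)
        obs = emit_continuous_observations(latent, 2, 0.05, seed=15)
        assignment = cluster_nodes(obs.data, seed=4)
        a = reduce_and_binarize(obs.data, assignment, normalize=False)
        scale = np.ones(obs.data.shape[1])
        scale[assignment.members(1)] = 5.0
        b = reduce_and_binarize(obs.data * scale, assignment, normalize=False)
        np.testing.assert_array_equal(a.values, b.values)

    def test_coverage_mismatch_rejected(self):
        clusters = ClusterAssignment(labels=np.array([1, 2]), k=2)
        with pytest.raises(ValueError):
            reduce_and_binarize(np.zeros((5, 3)), clusters)

    def test_cluster_ids_must_be_complete(self):
        with pytest.raises(ValueError, match="non-empty"):
            ClusterAssignment(labels=np.array([1, 1, 3]), k=3)


def latent_to_layers(latent, n_layers, nodes_per_cluster, noise_sd, seed, T_pad=0):
    """Stack one emission per layer from the same latent dynamics."""
    return {
        layer: emit_continuous_observations(
            latent, nodes_per_cluster, noise_sd, seed=seed + layer
        ).data
        for layer in range(1, n_layers + 1)
    }


class TestPerLayerSeries:
    def _meta(self, latent, n_layers, n_hidden):
        return LLMSeriesMeta(
            n_hidden=n_hidden,
            n_layers=n_layers,
            n_iterations=latent.shape[0],
            window_start=100,
            window_end=latent.shape[0],
        )

    def test_first_layer_excluded(self):
        latent = sample_mem_series(random_params(6, n=9, scale=0.3), 1200, seed=16)
        stacked = latent_to_layers(latent, n_layers=4, nodes_per_cluster=2, noise_sd=0.1, seed=20)
        out = per_layer_series(stacked, self._meta(latent, 4, 18))
        assert len(out) == 3
        assert [s.layer for s in out] == [2, 3, 4]

    def test_two_layers_boundary(self):
        latent = sample_mem_series(random_params(7, n=9, scale=0.3), 900, seed=17)
        stacked = latent_to_layers(latent, n_layers=2, nodes_per_cluster=2, noise_sd=0.1, seed=30)
        out = per_layer_series(stacked, self._meta(latent, 2, 18))
        assert len(out) == 1
        assert out[0].layer == 2

    def test_single_layer_rejected(self):
        latent = np.ones((300, 9), dtype=np.int8)
        with pytest.raises(ValueError, match="at least 2 layers"):
            per_layer_series({1: np.zeros((300, 18))},
                             LLMSeriesMeta(n_hidden=18, n_layers=1, n_iterations=300,
                                           window_start=0, window_end=300))


class TestCompositionExactness:
    def test_noiseless_llm_route_recovers_latent_exactly(self):
        """Noiseless duplicated channels -> window -> cluster -> binarize is lossless."""
        latent = sample_mem_series(random_params(8, n=9, scale=0.3), 2000, seed=18)
        obs = emit_continuous_observations(latent, nodes_per_cluster=6, noise_sd=0.0, seed=19)
        windowed = select_iteration_window(obs.data, 200, 2000)
        assignment = cluster_nodes(windowed, seed=5)
        out = reduce_and_binarize(windowed, assignment)
        # align recovered clusters to true channels through the truth map
        truth = latent[200:2000]
        aligned = np.empty_like(out.values)
        for c in range(1, 10):
            members = assignment.members(c)
            true_channels = obs.cluster_map[members]
            assert len(set(true_channels.tolist())) == 1  # pure cluster
            aligned[:, true_channels[0]] = out.values[:, c - 1]
        np.testing.assert_array_equal(aligned, truth)

    def test_noiseless_brain_route_recovers_latent(self):
        latent = sample_mem_series(random_params(9, n=9, scale=0.3), 1500, seed=20)
        # drop the (rare) sign-uniform rows: the across-node-mean threshold
        # cannot represent them by construction
        mixed = latent[np.abs(latent.sum(axis=1)) < 9]
        obs = emit_continuous_observations(
            mixed, 1, 0.0, seed=21, gain_range=(1.0, 1.0), offset_range=(0.0, 0.0)
        )
        out = binarize_brain_route(obs.data)
        np.testing.assert_array_equal(out.values, mixed)


class TestBinaryStateSeries:
    def test_rejects_non_pm1(self):
        with pytest.raises(ValueError):
            BinaryStateSeries(values=np.array([[1, 0]]))

    def test_array_protocol_and_labels(self):
        s = BinaryStateSeries(values=np.array([[1, -1], [-1, 1]]), source="brain-route")
        assert s.node_labels == ["n1", "n2"]
        np.testing.assert_array_equal(np.asarray(s), s.values)
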