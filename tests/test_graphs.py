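"""Spatial prior construction: transforms, pairwise stats, gated kernels."""

import numpy as np
import pytest

from msgm.graphs import (PCC_GUARD, RegionMap, TransformParams, batch_average,
                         build_graph_pair, flatten_node_matrix, global_graph,
                         graph_thresholds, local_graph, node_features,
                         pairwise_stats, stack_priors)


class TestBatchAverage:
    def test_idempotent_on_identical_items(self, rng):
        item = rng.random((4, 3, 7))
        batch = np.stack([item] * 5)
        np.testing.assert_allclose(batch_average(batch), item, rtol=1e-12)

    def test_opposite_pair_cancels(self, rng):
        v = rng.standard_normal((2, 3, 7))
        np.testing.assert_allclose(batch_average(np.stack([v, -v])), 0.0)

    def test_matches_summation_oracle(self, rng):
        batch = rng.random((5, 2, 3, 7))
        expect = sum(batch[i] for i in range(5)) / 5
        np.testing.assert_allclose(batch_average(batch), expect)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_average(np.zeros((0, 2, 3, 7)))


class TestNodeFeatures:
    def test_zero_weights_return_bias(self, rng):
        avg = rng.random((4, 3, 7))
        params = TransformParams(W=np.zeros((28, 4)), V=rng.random((3, 4)))
        np.testing.assert_array_equal(node_features(avg, params), params.V)

    def test_one_hot_selector_reproduces_columns(self, rng):
        avg = rng.random((2, 3, 7))
        Z = flatten_node_matrix(avg)
        W = np.zeros((14, 2))
        W[3, 0] = 1.0
        W[9, 1] = 1.0
        params = TransformParams(W=W, V=np.zeros((3, 2)))
        np.testing.assert_allclose(node_features(avg, params), Z[:, [3, 9]])

    def test_matches_naive_matmul_oracle(self, rng):
        avg = rng.random((3, 4, 7))
        params = TransformParams.init(4, 3, 7, rng)
        Z = flatten_node_matrix(avg)
        expect = np.empty((4, 3))
        for i in range(4):
            for j in range(3):
                expect[i, j] = sum(Z[i, m] * params.W[m, j] for m in range(21)) \
                    + params.V[i, j]
        np.testing.assert_allclose(node_features(avg, params), expect)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            node_features(rng.random((3, 4, 7)), TransformParams.init(4, 5, 7, rng))


class TestPairwiseStats:
    def test_identical_and_anticorrelated_nodes(self):
        u = np.array([1.0, -1.0, 2.0, -2.0])
        Z = np.vstack([u, u, -u])
        kappa, d, e = pairwise_stats(Z)
        assert kappa[0, 1] == pytest.approx(1.0, abs=1e-4)
        assert kappa[0, 2] == pytest.approx(-1.0, abs=1e-4)
        assert d[0, 1] == 0 and e[0, 1] == 0
        assert d[0, 2] == pytest.approx(2 * np.abs(u).sum())

    def test_matches_textbook_formula_oracle(self, rng):
        Z = rng.standard_normal((6, 4))
        kappa, d, e = pairwise_stats(Z)
        for i in range(6):
            for j in range(6):
                ui, uj = Z[i], Z[j]
                ni = (ui - ui.mean()) / (ui.std() + PCC_GUARD)
                nj = (uj - uj.mean()) / (uj.std() + PCC_GUARD)
                assert kappa[i, j] == pytest.approx(float(ni @ nj) / 4)
                assert d[i, j] == pytest.approx(np.abs(ui - uj).sum())
                assert e[i, j] == pytest.approx(np.linalg.norm(ui - uj))

    def test_constant_rows_guarded(self):
        kappa, _, _ = pairwise_stats(np.ones((3, 4)))
        assert np.all(np.isfinite(kappa))


class TestGlobalGraph:
    def test_sparsity_and_kernel_oracle(self, rng):
        Zp = rng.standard_normal((16, 6))
        W, diag = global_graph(Zp)
        c = 16
        off = ~np.eye(c, dtype=bool)
        n_pairs = c * (c - 1) // 2
        kappa_u = diag["kappa"][np.triu_indices(c, 1)]
        ties = np.sum(kappa_u == diag["kappa_theta"])
        assert (np.count_nonzero(W[off]) / 2) <= 0.25 * n_pairs + ties
        # every surviving weight equals the brute-force gated Gaussian kernel
        kap, man, euc = pairwise_stats(Zp)
        k_th, d_th, sigma = graph_thresholds(kap, man, euc)
        for i in range(c):
            for j in range(c):
                if i == j:
                    assert W[i, j] == 1.0
                elif kap[i, j] >= k_th and man[i, j] <= d_th:
                    assert W[i, j] == pytest.approx(
                        np.exp(-euc[i, j] ** 2 / (2 * sigma**2)))
                else:
                    assert W[i, j] == 0.0
        assert np.array_equal(W, W.T)
        assert W.min() >= 0 and W.max() <= 1 + 1e-12

    def test_identical_channels_get_unit_weight(self):
        base = np.array([0.3, -1.2, 0.5, 2.0])
        Zp = np.vstack([base, base, base + 5.0, -base])
        W, diag = global_graph(Zp)
        if diag["gate"][0, 1]:
            assert W[0, 1] == pytest.approx(1.0)

    def test_low_correlation_pair_gated_out(self, rng):
        Zp = rng.standard_normal((8, 5))
        W, diag = global_graph(Zp)
        kap = diag["kappa"]
        below = (kap < diag["kappa_theta"]) & ~np.eye(8, dtype=bool)
        assert np.all(W[below] == 0)

    def test_sigma_monotonicity_of_surviving_weights(self, rng):
        """Larger bandwidth never decreases a surviving kernel weight."""
        Zp = rng.standard_normal((10, 4))
        W, diag = global_graph(Zp)
        sigma2 = diag["sigma"] * 2
        W2 = np.where(diag["gate"],
                      np.exp(-diag["euclid"] ** 2 / (2 * sigma2**2)), 0.0)
        np.fill_diagonal(W2, 1.0)
        assert np.all(W2 >= W - 1e-12)


class TestLocalGraphAndStacking:
    def test_single_region_keeps_everything(self, rng):
        W, _ = global_graph(rng.standard_normal((6, 4)))
        np.testing.assert_array_equal(local_graph(W, np.zeros(6, int)), W)

    def test_singleton_regions_keep_only_diagonal(self, rng):
        W, _ = global_graph(rng.standard_normal((6, 4)))
        W_l = local_graph(W, np.arange(6))
        np.testing.assert_array_equal(W_l, np.diag(np.diag(W)))

    def test_support_inclusion_and_value_equality(self, rng):
        W, _ = global_graph(rng.standard_normal((14, 5)))
        regions = np.repeat(np.arange(7), 2)
        W_l = local_graph(W, regions)
        nz = W_l != 0
        assert np.all(W[nz] == W_l[nz])
        for i, j in zip(*np.nonzero(nz)):
            assert regions[i] == regions[j]

    def test_unmapped_channel_rejected(self, rng):
        W, _ = global_graph(rng.standard_normal((6, 4)))
        with pytest.raises(ValueError):
            local_graph(W, np.zeros(5, int))

    def test_stacking_duplicates_then_mutates_independently(self, rng):
        W, _ = global_graph(rng.standard_normal((5, 4)))
        W_l = local_graph(W, np.array([0, 0, 1, 1, 1]))
        G_g, G_l = stack_priors(W, W_l)
        assert G_g.shape == (2, 5, 5)
        np.testing.assert_array_equal(G_g[0], G_g[1])
        np.testing.assert_array_equal(G_g[0], W)
        np.testing.assert_array_equal(G_l[0], W_l)
        G_g[1][0, 1] = -99
        assert G_g[0][0, 1] == W[0, 1]


class TestRegionMap:
    def test_packaged_62_channel_partitions(self):
        from importlib import resources
        for name, n in [("7-region-62ch", 7), ("10-region-62ch", 10),
                        ("17-region-62ch", 17)]:
            path = resources.files("msgm.data.regions").joinpath(f"{name}.json")
            with resources.as_file(path) as p:
                rm = RegionMap.from_json(p)
            assert len(rm.mapping) == 62 and rm.n_regions == n

    def test_noncontiguous_ids_rejected(self):
        with pytest.raises(ValueError):
            RegionMap({"A": 0, "B": 2})

    def test_unknown_channel_label_raises(self):
        rm = RegionMap({"A": 0, "B": 1})
        with pytest.raises(KeyError, match="C"):
            rm.region_ids(["A", "C"])


def test_build_graph_pair_deterministic(rng):
    values = rng.random((6, 5, 8, 7))
    params = TransformParams.init(8, 5, 7, np.random.default_rng(3))
    regions = np.repeat(np.arange(4), 2)
    a = build_graph_pair(values, params, regions)
    b = build_graph_pair(values, params, regions)
    np.testing.assert_array_equal(a.W_global, b.W_global)
    np.testing.assert_array_equal(a.W_local, b.W_local)
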