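"""Chebyshev graph convolution and token fusion."""

import numpy as np
import pytest

from msgm.autodiff import Tensor
from msgm.fusion import (ChebGraphEncoder, GraphFusion, base_embedding,
                         chebyshev_basis, fuse_tokens, normalized_laplacian,
                         scaled_laplacian)
from msgm.nn import Linear


class TestNormalizedLaplacian:
    def test_diagonal_only_graph(self):
        L = normalized_laplacian(np.eye(4))
        np.testing.assert_allclose(L, -np.eye(4))

    def test_two_node_edge_closed_form(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        # L_sym = [[1,-1],[-1,1]], lambda_max = 2 -> L_hat = L_sym - I
        np.testing.assert_allclose(normalized_laplacian(W),
                                   np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_random_graph_spectrum_in_unit_interval(self, rng):
        A = rng.random((8, 8))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 1.0)
        eig = np.linalg.eigvalsh(normalized_laplacian(W))
        assert eig.min() >= -1 - 1e-9 and eig.max() <= 1 + 1e-9

    def test_isolated_node_row_zeroed(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        L = normalized_laplacian(W)
        np.testing.assert_array_equal(L[2], [0, 0, -1])  # -I contribution only

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError):
            normalized_laplacian(rng.random((4, 4)))

    def test_tape_version_matches_numpy(self, rng):
        A = rng.random((6, 6))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 1.0)
        np.testing.assert_allclose(scaled_laplacian(Tensor(W)).data,
                                   normalized_laplacian(W), atol=1e-10)


def random_graph(rng, c):
    A = rng.random((c, c))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 1.0)
    return W


class TestChebConv:
    def test_order_one_is_graph_independent_dense_layer(self, rng):
        enc = ChebGraphEncoder(order=1, depth=1, w_in=7, w_out=5, rng=rng)
        enc.biases[0].data[:] = 0.0
        F = rng.random((2, 3, 6, 7))
        out_a = enc(F, normalized_laplacian(random_graph(rng, 6))).data
        out_b = enc(F, normalized_laplacian(random_graph(rng, 6))).data
        np.testing.assert_allclose(out_a, out_b)
        expect = np.maximum(F @ enc.thetas[0][0].data, 0.0)
        np.testing.assert_allclose(out_a, expect)

    def test_matches_explicit_polynomial_expansion(self, rng):
        """Path graph, order 3: compare against dense polynomial-in-L oracle."""
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        np.fill_diagonal(W, 1.0)
        L = normalized_laplacian(W)
        enc = ChebGraphEncoder(order=3, depth=1, w_in=4, w_out=2, rng=rng)
        F = rng.standard_normal((1, 2, 3, 4))
        out = enc(F, L).data
        T = [np.eye(3), L, 2 * L @ L - np.eye(3)]
        acc = sum(T[i] @ F @ enc.thetas[0][i].data for i in range(3))
        expect = np.maximum(acc - enc.biases[0].data, 0.0)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_outputs_nonnegative(self, rng):
        enc = ChebGraphEncoder(order=3, depth=2, w_in=7, w_out=4, rng=rng)
        out = enc(rng.standard_normal((2, 2, 5, 7)),
                  normalized_laplacian(random_graph(rng, 5))).data
        assert out.min() >= 0.0

    def test_edge_weight_scaling_invariance(self, rng):
        """Degree normalization makes the conv invariant to W -> 2W."""
        W = random_graph(rng, 6)
        enc = ChebGraphEncoder(order=3, depth=1, w_in=7, w_out=4, rng=rng)
        F = rng.random((1, 2, 6, 7))
        out1 = enc(F, normalized_laplacian(W)).data
        out2 = enc(F, normalized_laplacian(2 * W)).data
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_chebyshev_recurrence(self, rng):
        L = normalized_laplacian(random_graph(rng, 5))
        basis = chebyshev_basis(L, 4)
        np.testing.assert_allclose(basis[3].data,
                                   2 * L @ basis[2].data - basis[1].data)

    def test_gradients_reach_parameters(self, rng):
        enc = ChebGraphEncoder(order=2, depth=2, w_in=7, w_out=3, rng=rng)
        out = enc(rng.random((1, 2, 4, 7)),
                  normalized_laplacian(random_graph(rng, 4)))
        (out * out).sum().backward()
        assert all(t.grad is not None for layer in enc.thetas for t in layer)


class TestBaseEmbeddingAndFusion:
    def test_zero_weights_give_bias_rows(self, rng):
        lp = Linear(6 * 7, 5, rng)
        lp.weight.data[:] = 0.0
        lp.bias.data[:] = 3.0
        out = base_embedding(rng.random((2, 4, 6, 7)), lp).data
        assert out.shape == (8, 5)
        np.testing.assert_allclose(out, 3.0)

    def test_matches_matmul_oracle(self, rng):
        lp = Linear(12, 3, rng)
        F = rng.random((2, 2, 4, 3))
        out = base_embedding(F, lp).data
        expect = F.reshape(4, 12) @ lp.weight.data + lp.bias.data
        np.testing.assert_allclose(out, expect)

    def test_fuse_tokens_mean_properties(self, rng):
        a = rng.standard_normal((6, 4))
        np.testing.assert_allclose(fuse_tokens(a, a, a).data, a)
        np.testing.assert_allclose(fuse_tokens(a, -a, np.zeros_like(a)).data, 0.0,
                                   atol=1e-15)
        b, c = rng.standard_normal((2, 6, 4))
        np.testing.assert_allclose(fuse_tokens(a, b, c).data, (a + b + c) / 3)

    def test_fuse_tokens_permutation_equivariant(self, rng):
        a, b, c = rng.standard_normal((3, 6, 4))
        perm = rng.permutation(6)
        np.testing.assert_allclose(fuse_tokens(a, b, c).data[perm],
                                   fuse_tokens(a[perm], b[perm], c[perm]).data)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_tokens(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros((3, 2)))


def test_graph_fusion_output_shapes_and_variants(rng):
    c, f, h = 6, 7, 8
    W = random_graph(rng, c)
    L = normalized_laplacian(W)
    F = rng.random((3, 4, c, f))
    full = GraphFusion(c, f, h, order=2, w_out=3, rng=rng)
    s_g, s_l = full(F, (L, L), (L, L))
    assert s_g.shape == (3, 4, h) and s_l.shape == (3, 4, h)

    single = GraphFusion(c, f, h, order=2, w_out=3,
                         rng=np.random.default_rng(0), single_gcn=True)
    s_g, _ = single(F, (L, L), (L, L))
    assert s_g.shape == (3, 4, h)

    bypass = GraphFusion(c, f, h, order=2, w_out=3,
                         rng=np.random.default_rng(0), no_fusion=True)
    s_g, s_l = bypass(F, (L, L), (L, L))
    np.testing.assert_array_equal(s_g.data, s_l.data)
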