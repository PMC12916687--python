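"""Selective-scan recurrence, block causality, residual stack."""

import numpy as np
import pytest

from msgm.autodiff import Tensor, no_grad
from msgm.mamba import MambaBlock, MSSTStack, RMSNorm, rmsnorm, selective_scan


def naive_scan(v, delta, B, C, A, D):
    """Per-step reference recurrence, plain Python loops over time."""
    b, n, d_inner = v.shape
    d_state = A.shape[1]
    y = np.zeros_like(v)
    for bi in range(b):
        x = np.zeros((d_inner, d_state))
        for t in range(n):
            x = np.exp(delta[bi, t][:, None] * A) * x \
                + delta[bi, t][:, None] * B[bi, t][None, :] * v[bi, t][:, None]
            y[bi, t] = x @ C[bi, t] + D * v[bi, t]
    return y


def random_scan_inputs(rng, b=2, n=8, d_inner=6, d_state=4):
    v = rng.standard_normal((b, n, d_inner))
    delta = rng.uniform(0.01, 0.5, (b, n, d_inner))
    B = rng.standard_normal((b, n, d_state))
    C = rng.standard_normal((b, n, d_state))
    A = -rng.uniform(0.1, 3.0, (d_inner, d_state))
    D = rng.standard_normal(d_inner)
    return v, delta, B, C, A, D


class TestRmsNorm:
    def test_constant_positive_vector_gives_ones(self):
        x = np.full((2, 3, 4), 2.5)
        np.testing.assert_allclose(rmsnorm(x, np.ones(4)).data, 1.0, atol=1e-6)

    def test_positive_scale_invariance(self, rng):
        x = rng.standard_normal((2, 3, 8))
        g = np.ones(8)
        # invariance holds up to the 1e-6 epsilon inside the norm
        np.testing.assert_allclose(rmsnorm(7.3 * x, g).data,
                                   rmsnorm(x, g).data, atol=1e-5)

    def test_matches_direct_formula(self, rng):
        x = rng.standard_normal((5,))
        g = rng.standard_normal(5)
        expect = x / np.sqrt(np.mean(x**2) + 1e-6) * g
        np.testing.assert_allclose(rmsnorm(x, g).data, expect)


class TestSelectiveScan:
    def test_single_step_closed_form(self, rng):
        v, delta, B, C, A, D = random_scan_inputs(rng, n=1)
        y = selective_scan(v, delta, B, C, A, D).data
        x1 = delta[:, 0][:, :, None] * B[:, 0][:, None, :] * v[:, 0][:, :, None]
        expect = np.einsum("bds,bs->bd", x1, C[:, 0]) + D * v[:, 0]
        np.testing.assert_allclose(y[:, 0], expect, atol=1e-12)

    def test_zero_decay_reduces_to_accumulator(self, rng):
        v, delta, B, C, _, D = random_scan_inputs(rng, n=5)
        A = np.zeros((6, 4))
        y = selective_scan(v, delta, B, C, A, D).data
        acc = np.zeros((2, 6, 4))
        for t in range(5):
            acc = acc + delta[:, t][:, :, None] * B[:, t][:, None, :] \
                * v[:, t][:, :, None]
            expect = np.einsum("bds,bs->bd", acc, C[:, t]) + D * v[:, t]
            np.testing.assert_allclose(y[:, t], expect, atol=1e-12)

    def test_matches_sequential_oracle_on_long_sequences(self, rng):
        for _ in range(5):
            args = random_scan_inputs(rng, b=3, n=32, d_inner=8, d_state=5)
            y = selective_scan(*args).data
            ref = naive_scan(*args)
            np.testing.assert_allclose(y, ref, rtol=1e-5, atol=1e-10)

    def test_nonpositive_delta_asserts(self, rng):
        v, delta, B, C, A, D = random_scan_inputs(rng)
        delta[0, 0, 0] = 0.0
        with pytest.raises(AssertionError):
            selective_scan(v, delta, B, C, A, D)

    def test_strict_causality(self, rng):
        v, delta, B, C, A, D = random_scan_inputs(rng, b=1, n=6)
        y0 = selective_scan(v, delta, B, C, A, D).data
        v2 = v.copy()
        v2[0, 3] += 10.0
        y1 = selective_scan(v2, delta, B, C, A, D).data
        np.testing.assert_array_equal(y0[0, :3], y1[0, :3])
        assert not np.allclose(y0[0, 3:], y1[0, 3:])


class TestMambaBlock:
    def test_shape_preserved(self, rng):
        block = MambaBlock(h=8, rng=rng)
        out = block(rng.standard_normal((2, 5, 8)))
        assert out.data.shape == (2, 5, 8)

    def test_causality_perturbation_sweep(self, rng):
        n = 8
        block = MambaBlock(h=6, rng=rng)
        x = rng.standard_normal((1, n, 6))
        with no_grad():
            base = block(x).data
            for t in range(n):
                xp = x.copy()
                xp[0, t] += 1.0
                out = block(xp).data
                np.testing.assert_allclose(out[0, :t], base[0, :t], atol=1e-12)
                assert not np.allclose(out[0, t], base[0, t])

    def test_zero_input_with_zero_biases_maps_to_zero(self, rng):
        block = MambaBlock(h=6, rng=rng)
        out = block(np.zeros((2, 4, 6))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_scan_counter_linear_in_sequence_length(self, rng):
        block = MambaBlock(h=6, rng=rng)
        block(rng.standard_normal((2, 4, 6)))
        assert block.scan_step_count == 4
        block(rng.standard_normal((2, 8, 6)))
        assert block.scan_step_count == 12


class TestMSSTStack:
    def test_zeroed_block_reduces_to_final_norm(self, rng):
        stack = MSSTStack(h=6, M=1, rng=rng)
        stack.blocks[0].out_proj.weight.data[:] = 0.0
        x = rng.standard_normal((2, 5, 6))
        out = stack(x).data
        np.testing.assert_allclose(out, rmsnorm(x, stack.final_norm.gain).data)

    def test_single_block_equals_manual_composition(self, rng):
        stack = MSSTStack(h=6, M=1, rng=rng)
        stack.eval()
        x = rng.standard_normal((2, 5, 6))
        out = stack(x).data
        inner = stack.blocks[0](rmsnorm(x, stack.norms[0].gain)).data + x
        expect = rmsnorm(inner, stack.final_norm.gain).data
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_output_finite_for_huge_inputs(self, rng):
        stack = MSSTStack(h=6, M=2, rng=rng)
        out = stack(1e6 * rng.standard_normal((1, 4, 6))).data
        assert np.all(np.isfinite(out))

    def test_stack_causality(self, rng):
        stack = MSSTStack(h=5, M=2, rng=rng)
        stack.eval()
        x = rng.standard_normal((1, 6, 5))
        base = stack(x).data
        xp = x.copy()
        xp[0, 2] += 3.0
        out = stack(xp).data
        np.testing.assert_allclose(out[0, :2], base[0, :2], atol=1e-12)
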