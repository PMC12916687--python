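"""Selective state-space temporal modeling of token sequences.

A residual stack of pre-normalized blocks processes each token sequence
(b, n, h). Every block expands the hidden width, runs a causal depthwise
convolution + SiLU, then a selective scan

    x_t = exp(Delta_t * A) . x_{t-1} + Delta_t * B_t . v_t
    y_t = C_t . x_t + D . v_t

with diagonal negative A (S4D-real initialization) and input-dependent
Delta_t, B_t, C_t (Delta through a dt_rank bottleneck + softplus, so
Delta_t > 0 and exp(Delta_t A) in (0, 1]). A SiLU gating branch multiplies
the scan output before the closing projection. The recurrence runs exactly n
steps — linear time in the sequence length.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Linear, Module, dropout

__all__ = ["rmsnorm", "RMSNorm", "selective_scan", "MambaBlock", "MSSTStack"]

RMS_EPS = 1e-6


def rmsnorm(x: Tensor | np.ndarray, gain: Tensor | np.ndarray) -> Tensor:
    """Per-token root-mean-square normalization: x / sqrt(mean(x^2) + eps) * gain."""
    x = Tensor._wrap(x)
    gain = Tensor._wrap(gain)
    ms = (x * x).mean(axis=-1, keepdims=True)
    return x * (ms + RMS_EPS) ** -0.5 * gain


class RMSNorm(Module):
    def __init__(self, h: int):
        self.gain = Tensor(np.ones(h), requires_grad=True)

    def forward(self, x):
        return rmsnorm(x, self.gain)


def selective_scan(v: Tensor | np.ndarray, delta: Tensor | np.ndarray,
                   B: Tensor | np.ndarray, C: Tensor | np.ndarray,
                   A: Tensor | np.ndarray, D: Tensor | np.ndarray) -> Tensor:
    """Run the selective-scan recurrence.

    Shapes: v, delta (b, n, d_inner); B, C (b, n, d_state); A (d_inner,
    d_state) with all entries < 0; D (d_inner). The state starts at zero and
    the Euler-discretized input term Delta_t * B_t * v_t follows the
    recurrence as written. Strictly causal; returns y of shape v.
    """
    v, delta, B, C, A, D = map(Tensor._wrap, (v, delta, B, C, A, D))
    b, n, d_inner = v.shape
    d_state = A.shape[1]
    if np.any(delta.data <= 0):
        raise AssertionError("selective_scan requires Delta_t > 0")
    x = Tensor(np.zeros((b, d_inner, d_state)))
    ys = []
    for t in range(n):
        d_t = delta[:, t, :].reshape(b, d_inner, 1)
        v_t = v[:, t, :].reshape(b, d_inner, 1)
        B_t = B[:, t, :].reshape(b, 1, d_state)
        C_t = C[:, t, :].reshape(b, 1, d_state)
        x = (d_t * A).exp() * x + d_t * B_t * v_t
        y_t = (x * C_t).sum(axis=-1) + D * v[:, t, :]
        ys.append(y_t)
    return ad.stack(ys, axis=1)


class MambaBlock(Module):
    """One selective-state-space block (projections, causal depthwise conv,
    scan, gating). Maintains a scan-step counter used by linear-time tests."""

    def __init__(self, h: int, rng: np.random.Generator, *, expansion: int = 2,
                 d_state: int = 16, kernel: int = 4, dt_rank: int | None = None,
                 dt_min: float = 1e-3, dt_max: float = 1e-1):
        if kernel < 1:
            raise ValueError("conv kernel must be >= 1")
        self.h = h
        self.d_inner = expansion * h
        self.d_state = d_state
        self.kernel = kernel
        self.dt_rank = dt_rank if dt_rank is not None else math.ceil(h / 16)
        self.in_proj = Linear(h, 2 * self.d_inner, rng, bias=False)
        self.conv_weight = Tensor(
            rng.uniform(-1, 1, size=(kernel, self.d_inner)) / math.sqrt(kernel),
            requires_grad=True)
        self.conv_bias = Tensor(np.zeros(self.d_inner), requires_grad=True)
        self.x_proj = Linear(self.d_inner, self.dt_rank + 2 * d_state, rng, bias=False)
        self.dt_proj = Linear(self.dt_rank, self.d_inner, rng)
        # softplus(dt_bias) lands in [dt_min, dt_max] (log-uniform)
        dt = np.exp(rng.uniform(math.log(dt_min), math.log(dt_max),
                                size=self.d_inner))
        self.dt_proj.bias = Tensor(dt + np.log(-np.expm1(-dt)), requires_grad=True)
        # S4D-real: A[:, k] = -(k + 1), stored as log magnitude
        self.A_log = Tensor(
            np.tile(np.log(np.arange(1, d_state + 1)), (self.d_inner, 1)),
            requires_grad=True)
        self.D = Tensor(np.ones(self.d_inner), requires_grad=True)
        self.out_proj = Linear(self.d_inner, h, rng, bias=False)
        self.scan_step_count = 0

    def _causal_conv(self, x: Tensor) -> Tensor:
        """Depthwise causal 1-D convolution along the token axis (left pad
        kernel-1, so output t only sees inputs <= t)."""
        b, n, d = x.shape
        pad = Tensor(np.zeros((b, self.kernel - 1, d)))
        xp = ad.concat([pad, x], axis=1) if self.kernel > 1 else x
        acc = None
        for j in range(self.kernel):
            term = xp[:, j:j + n, :] * self.conv_weight[j]
            acc = term if acc is None else acc + term
        return acc + self.conv_bias

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = Tensor._wrap(x)
        b, n, _ = x.shape
        xz = self.in_proj(x)
        a = xz[:, :, :self.d_inner]
        z = xz[:, :, self.d_inner:]
        a = self._causal_conv(a).silu()
        proj = self.x_proj(a)
        delta = self.dt_proj(proj[:, :, :self.dt_rank]).softplus()
        B = proj[:, :, self.dt_rank:self.dt_rank + self.d_state]
        C = proj[:, :, self.dt_rank + self.d_state:]
        A = -self.A_log.exp()
        y = selective_scan(a, delta, B, C, A, self.D)
        self.scan_step_count += n
        return self.out_proj(y * z.silu())


class MSSTStack(Module):
    """Residual pre-norm chain of M blocks, closed by a final RMSNorm:
    x_m = Block_m(RMSNorm(x_{m-1})) + x_{m-1}. Dropout is applied to each
    block output before the residual add (train time only)."""

    def __init__(self, h: int, M: int, rng: np.random.Generator, *,
                 dropout_p: float = 0.25, **block_kwargs):
        if M < 1:
            raise ValueError("need at least one block")
        self.blocks = [MambaBlock(h, rng, **block_kwargs) for _ in range(M)]
        self.norms = [RMSNorm(h) for _ in range(M)]
        self.final_norm = RMSNorm(h)
        self.dropout_p = dropout_p

    def forward(self, x: Tensor | np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        x = Tensor._wrap(x)
        train = self.training and rng is not None
        for norm, block in zip(self.norms, self.blocks):
            out = block(norm(x))
            out = dropout(out, self.dropout_p, rng, train)
            x = out + x
        return self.final_norm(x)

    @property
    def scan_step_count(self) -> int:
        return sum(b.scan_step_count for b in self.blocks)

    def reset_scan_counter(self) -> None:
        for b in self.blocks:
            b.scan_step_count = 0
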