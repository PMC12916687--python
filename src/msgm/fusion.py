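"""Chebyshev graph encoders and token-embedding fusion.

Each temporal scale is encoded by four spectral graph convolutions — shallow
(1 layer) and deep (2 layers) variants applied to the global and the local
adjacency — plus a graph-free linear base embedding of the flattened
features. Convolutions follow the ChebyNet form

    Phi(F, A) = ReLU( sum_{i<I} T_i(L_hat) F theta_i - B ),

with T_i the Chebyshev polynomials of the rescaled normalized Laplacian
L_hat = 2 L_sym / lambda_max - I. Per stream (global/local) the base
embedding and the two encoder outputs (projected from channel space to the
hidden width h) are fused by an unweighted elementwise mean, producing the
token sequences handed to the temporal model.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Linear, Module

__all__ = [
    "normalized_laplacian", "scaled_laplacian", "chebyshev_basis",
    "ChebGraphEncoder", "base_embedding", "fuse_tokens", "GraphFusion",
]


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """Rescaled symmetric normalized Laplacian L_hat = 2 L_sym/lambda_max - I.

    L_sym = I - D^{-1/2} W D^{-1/2}; rows/columns of isolated (zero-degree)
    nodes are zeroed. lambda_max is computed exactly (graphs here are small).
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    deg = W.sum(axis=1)
    dinv = np.where(deg > 0, deg, 1.0) ** -0.5
    L = np.eye(W.shape[0]) - dinv[:, None] * W * dinv[None, :]
    iso = deg <= 0
    L[iso, :] = 0.0
    L[:, iso] = 0.0
    lam = float(np.linalg.eigvalsh(L).max())
    if lam < 1e-12:
        return -np.eye(W.shape[0])
    return 2.0 * L / lam - np.eye(W.shape[0])


def scaled_laplacian(W: Tensor) -> Tensor:
    """Differentiable L_hat for adjacencies with strictly positive degrees
    (the graph priors here carry a unit diagonal). lambda_max is treated as a
    constant of the backward pass (exact eigensolve on the current values)."""
    c = W.shape[0]
    eye = Tensor(np.eye(c))
    deg = W.sum(axis=1)
    if np.any(deg.data <= 0):
        raise ValueError("scaled_laplacian requires positive degrees")
    dinv = deg ** -0.5
    L = eye - W * dinv.reshape(c, 1) * dinv.reshape(1, c)
    lam = float(np.linalg.eigvalsh(L.data).max())
    if lam < 1e-12:
        return eye * -1.0
    return L * (2.0 / lam) - eye


def chebyshev_basis(L_hat: Tensor | np.ndarray, order: int) -> list[Tensor]:
    """T_0..T_{order-1} of L_hat via the three-term recurrence."""
    L_hat = Tensor._wrap(L_hat)
    c = L_hat.shape[0]
    basis = [Tensor(np.eye(c))]
    if order > 1:
        basis.append(L_hat)
    for _ in range(2, order):
        basis.append((L_hat @ basis[-1]) * 2.0 - basis[-2])
    return basis[:order]


class ChebGraphEncoder(Module):
    """`depth` stacked Chebyshev convolution layers of order `order`.

    Layer widths run w_in -> w_out (-> w_out for the deep variant). Eq-form
    per layer: ReLU(sum_i T_i(L_hat) F theta_i - B), with the bias subtracted
    as a learned per-feature term.
    """

    def __init__(self, order: int, depth: int, w_in: int, w_out: int,
                 rng: np.random.Generator):
        if order < 1 or depth < 1:
            raise ValueError("order and depth must be >= 1")
        self.order = order
        self.depth = depth
        self.thetas: list[list[Tensor]] = []
        self.biases: list[Tensor] = []
        win = w_in
        for _ in range(depth):
            limit = np.sqrt(6.0 / (win * order + w_out))
            self.thetas.append([
                Tensor(rng.uniform(-limit, limit, size=(win, w_out)),
                       requires_grad=True)
                for _ in range(order)])
            self.biases.append(Tensor(np.zeros(w_out), requires_grad=True))
            win = w_out

    def forward(self, F: Tensor | np.ndarray, L_hat: Tensor | np.ndarray) -> Tensor:
        """F: (b, n, c, w_in) node features; returns (b, n, c, w_out)."""
        x = Tensor._wrap(F)
        basis = chebyshev_basis(L_hat, self.order)
        for thetas, bias in zip(self.thetas, self.biases):
            acc = None
            for T_i, theta in zip(basis, thetas):
                term = (T_i @ x) @ theta
                acc = term if acc is None else acc + term
            x = (acc - bias).relu()
        return x


def base_embedding(F: Tensor | np.ndarray, lp: Linear) -> Tensor:
    """Flatten (b, n, c, f) -> (b*n, c*f) and project to the hidden width."""
    x = Tensor._wrap(F)
    b, n, c, f = x.shape
    return lp(x.reshape(b * n, c * f))


def fuse_tokens(base: Tensor | np.ndarray, shallow: Tensor | np.ndarray,
                deep: Tensor | np.ndarray) -> Tensor:
    """Unweighted elementwise mean of the three (b*n, h) embeddings."""
    base, shallow, deep = map(Tensor._wrap, (base, shallow, deep))
    if base.shape != shallow.shape or base.shape != deep.shape:
        raise ValueError("fuse_tokens inputs must share a shape")
    return (base + shallow + deep) * (1.0 / 3.0)


class GraphFusion(Module):
    """The four graph encoders + base embedding + per-stream projection heads.

    Weights are shared across temporal scales (the encoder shapes do not
    depend on n_k). `single_gcn` replaces the shallow/deep pair by one
    depth-1 encoder per stream; `no_fusion` returns the base embedding alone.
    """

    def __init__(self, c: int, f: int, h: int, order: int, w_out: int,
                 rng: np.random.Generator, *, depths: tuple[int, int] = (1, 2),
                 single_gcn: bool = False, no_fusion: bool = False):
        self.c, self.f, self.h, self.w_out = c, f, h, w_out
        self.single_gcn = single_gcn
        self.no_fusion = no_fusion
        self.lp = Linear(c * f, h, rng)
        if not no_fusion:
            d_shallow, d_deep = depths
            self.enc_shallow_g = ChebGraphEncoder(order, d_shallow, f, w_out, rng)
            self.enc_shallow_l = ChebGraphEncoder(order, d_shallow, f, w_out, rng)
            if not single_gcn:
                self.enc_deep_g = ChebGraphEncoder(order, d_deep, f, w_out, rng)
                self.enc_deep_l = ChebGraphEncoder(order, d_deep, f, w_out, rng)
            self.proj_g = Linear(c * w_out, h, rng)
            self.proj_l = Linear(c * w_out, h, rng)

    def _project(self, enc_out: Tensor, head: Linear) -> Tensor:
        b, n, c, w = enc_out.shape
        return head(enc_out.reshape(b * n, c * w))

    def forward(self, F: Tensor | np.ndarray, L_global: tuple, L_local: tuple
                ) -> tuple[Tensor, Tensor]:
        """Returns the global and local token sequences, each (b, n, h).

        L_global/L_local are the (slice-1, slice-2) rescaled Laplacians of the
        stacked graph priors; shallow encoders read slice 1, deep slice 2.
        """
        x = Tensor._wrap(F)
        b, n, _, _ = x.shape
        H = base_embedding(x, self.lp)
        if self.no_fusion:
            s = H.reshape(b, n, self.h)
            return s, s
        sh_g = self._project(self.enc_shallow_g(x, L_global[0]), self.proj_g)
        sh_l = self._project(self.enc_shallow_l(x, L_local[0]), self.proj_l)
        if self.single_gcn:
            s_g = (H + sh_g) * 0.5
            s_l = (H + sh_l) * 0.5
        else:
            dp_g = self._project(self.enc_deep_g(x, L_global[1]), self.proj_g)
            dp_l = self._project(self.enc_deep_l(x, L_local[1]), self.proj_l)
            s_g = fuse_tokens(H, sh_g, dp_g)
            s_l = fuse_tokens(H, sh_l, dp_l)
        return s_g.reshape(b, n, self.h), s_l.reshape(b, n, self.h)
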