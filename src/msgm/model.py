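"""End-to-end classifier: multi-scale rPSD tensors -> graph priors -> token
fusion -> selective-scan temporal stack -> pooled embedding -> linear head.

Per batch and per scale the graph priors are rebuilt from the current batch's
features and the current learnable transform; gradients flow through the
Gaussian-kernel weights while the data-driven thresholds (percentile gates,
kernel bandwidth, Laplacian lambda_max) are treated as constants of the
backward pass. At evaluation time the graphs frozen from the last training
batch are reused, so no statistics of the evaluation data leak across
samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fusion import GraphFusion, scaled_laplacian
from .graphs import graph_thresholds, pairwise_stats, stack_priors
from .mamba import MSSTStack
from .nn import Linear, Module, xavier_uniform

__all__ = ["ModelConfig", "MSGMModel", "pool_and_fuse", "classify", "ablate",
           "ABLATION_FLAGS"]

logger = logging.getLogger(__name__)

ABLATION_FLAGS = ("no_temporal_multiscale", "no_spatial_multiscale",
                  "single_gcn", "no_fusion", "no_mamba")


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters (defaults follow the published setup:
    h=32, one temporal block, d_state=16, conv kernel 4, GCN depths [1, 2],
    dropout 0.25)."""

    c: int = 16
    f: int = 7
    n_k: tuple[int, ...] = (9, 4)        # tokens per scale (from segmentation)
    d_out: int = 2
    h: int = 32
    M: int = 1
    cheb_order: int = 3
    gcn_depths: tuple[int, int] = (1, 2)
    w_out: int = 8                        # encoder output width per node
    d_state: int = 16
    conv_kernel: int = 4
    expansion: int = 2
    dropout: float = 0.25
    feature_type: str = "rpsd"            # rpsd | psd | de
    share_streams: bool = True            # one temporal stack for all streams
    # ablation switches (at most one active)
    no_temporal_multiscale: bool = False
    no_spatial_multiscale: bool = False
    single_gcn: bool = False
    no_fusion: bool = False
    no_mamba: bool = False

    @property
    def dt_rank(self) -> int:
        return math.ceil(self.h / 16)

    def __post_init__(self):
        if sum(getattr(self, flag) for flag in ABLATION_FLAGS) > 1:
            raise ValueError("at most one ablation flag may be set")
        if self.feature_type not in ("rpsd", "psd", "de"):
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.no_temporal_multiscale and len(self.n_k) > 1:
            # keep only the longest window (fewest tokens)
            object.__setattr__(self, "n_k", (min(self.n_k),))


def ablate(cfg: ModelConfig, flag: str) -> ModelConfig:
    """Return a copy of the config with exactly one ablation switch active."""
    if flag not in ABLATION_FLAGS:
        raise ValueError(f"unknown ablation flag {flag!r}; choose from {ABLATION_FLAGS}")
    if any(getattr(cfg, f) for f in ABLATION_FLAGS):
        raise ValueError("config already carries an ablation flag")
    return replace(cfg, **{flag: True})


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    return x * ((x * x).sum(axis=-1, keepdims=True) + eps) ** -0.5


def pool_and_fuse(stream_outputs: list[dict[str, Tensor]]) -> Tensor:
    """Collapse per-scale global/local sequences into one (b, h) embedding.

    Per stream and scale: mean over the token axis, L2-normalize rows;
    average global & local; mean over scales.
    """
    per_scale = []
    for streams in stream_outputs:
        g = l2_normalize(Tensor._wrap(streams["global"]).mean(axis=1))
        l = l2_normalize(Tensor._wrap(streams["local"]).mean(axis=1))
        per_scale.append((g + l) * 0.5)
    acc = per_scale[0]
    for s in per_scale[1:]:
        acc = acc + s
    return acc * (1.0 / len(per_scale))


def classify(x_final: Tensor | np.ndarray, W: Tensor | np.ndarray,
             b: Tensor | np.ndarray) -> Tensor:
    """Linear logits y = x W + b; softmax only happens in the loss/inference."""
    return Tensor._wrap(x_final) @ Tensor._wrap(W) + Tensor._wrap(b)


class MSGMModel(Module):
    def __init__(self, cfg: ModelConfig, region_ids: np.ndarray,
                 rng: np.random.Generator):
        region_ids = np.asarray(region_ids)
        if region_ids.shape[0] != cfg.c:
            raise ValueError("region ids must cover every channel")
        self.cfg = cfg
        self.region_ids = region_ids
        self.same_region = region_ids[:, None] == region_ids[None, :]
        # per-scale learnable graph transform (shape depends on n_k)
        self.transform_W = [xavier_uniform(rng, cfg.f * nk, nk) for nk in cfg.n_k]
        self.transform_V = [Tensor(np.zeros((cfg.c, nk)), requires_grad=True)
                            for nk in cfg.n_k]
        self.fusion = GraphFusion(
            cfg.c, cfg.f, cfg.h, cfg.cheb_order, cfg.w_out, rng,
            depths=cfg.gcn_depths, single_gcn=cfg.single_gcn,
            no_fusion=cfg.no_fusion)
        if not cfg.no_mamba:
            self.stack = MSSTStack(
                cfg.h, cfg.M, rng, dropout_p=cfg.dropout,
                expansion=cfg.expansion, d_state=cfg.d_state,
                kernel=cfg.conv_kernel, dt_rank=cfg.dt_rank)
        else:
            self.stack = None
        self.head_W = xavier_uniform(rng, cfg.h, cfg.d_out)
        self.head_b = Tensor(np.zeros(cfg.d_out), requires_grad=True)
        # eval-time frozen graphs, refreshed on every training forward
        self.frozen_graphs: list[dict] | None = None

    # -- graph construction ---------------------------------------------------

    def _build_graphs(self, values: np.ndarray, k: int) -> dict:
        """Differentiable per-batch graph rebuild for scale k. Gates,
        thresholds, sigma and lambda_max are detached constants."""
        cfg = self.cfg
        b, n_k, c, f = values.shape
        avg = Tensor(values.mean(axis=0))                       # constant input
        Z = avg.transpose(1, 0, 2).reshape(c, n_k * f)
        Zp = Z @ self.transform_W[k] + self.transform_V[k]
        kappa, manhattan, euclid = pairwise_stats(Zp.data)
        kappa_theta, d_theta, sigma = graph_thresholds(kappa, manhattan, euclid)
        gate = (kappa >= kappa_theta) & (manhattan <= d_theta)
        np.fill_diagonal(gate, False)
        sq = (Zp * Zp).sum(axis=1, keepdims=True)
        sqdist = sq + sq.reshape(1, c) - (Zp @ Zp.transpose(1, 0)) * 2.0
        if sigma <= 0:
            sigma = 1.0
        kernel = (sqdist * (-1.0 / (2.0 * sigma**2))).exp()
        eye = Tensor(np.eye(c))
        W_g = kernel * Tensor(gate.astype(float)) + eye
        local_gate = gate & self.same_region
        if cfg.no_spatial_multiscale:
            W_l = W_g
        else:
            W_l = kernel * Tensor(local_gate.astype(float)) + eye
        L_g = scaled_laplacian(W_g)
        L_l = scaled_laplacian(W_l)
        logger.debug("scale %d batch graph: sigma=%.4g kappa_theta=%.4g "
                     "d_theta=%.4g edges=%d", k, sigma, kappa_theta, d_theta,
                     int(gate.sum() // 2))
        return {"W_global": W_g, "W_local": W_l, "L_global": L_g, "L_local": L_l,
                "diagnostics": {"sigma": sigma, "kappa_theta": kappa_theta,
                                 "d_theta": d_theta}}

    def graph_pairs(self) -> list[dict]:
        """Frozen per-scale adjacencies (numpy) from the last training batch,
        stacked into the duplicated (2, c, c) prior form."""
        if self.frozen_graphs is None:
            raise RuntimeError("no graphs frozen yet: run a training forward first")
        out = []
        for g in self.frozen_graphs:
            G_g, G_l = stack_priors(g["W_global"], g["W_local"])
            out.append({"G_global": G_g, "G_local": G_l,
                        "diagnostics": g["diagnostics"]})
        return out

    # -- forward --------------------------------------------------------------

    def forward(self, features: list[np.ndarray],
                rng: np.random.Generator | None = None) -> Tensor:
        """features: one (b, n_k, c, f) array per scale -> logits (b, d_out)."""
        cfg = self.cfg
        if len(features) != len(cfg.n_k):
            raise ValueError(f"expected {len(cfg.n_k)} scale tensors, "
                             f"got {len(features)}")
        stream_outputs = []
        frozen = [] if self.training else None
        for k, values in enumerate(features):
            values = np.asarray(values, dtype=np.float64)
            if self.training:
                g = self._build_graphs(values, k)
                frozen.append({"W_global": g["W_global"].data.copy(),
                               "W_local": g["W_local"].data.copy(),
                               "diagnostics": g["diagnostics"]})
                L_global = (g["L_global"], g["L_global"])
                L_local = (g["L_local"], g["L_local"])
            else:
                if self.frozen_graphs is None:
                    raise RuntimeError(
                        "evaluation before any training forward: no frozen graphs")
                fg = self.frozen_graphs[k]
                L_g = scaled_laplacian(Tensor(fg["W_global"]))
                L_l = scaled_laplacian(Tensor(fg["W_local"]))
                L_global, L_local = (L_g, L_g), (L_l, L_l)
            s_g, s_l = self.fusion(values, L_global, L_local)
            if self.stack is not None:
                s_g = self.stack(s_g, rng)
                s_l = self.stack(s_l, rng)
            stream_outputs.append({"global": s_g, "local": s_l})
        if self.training:
            self.frozen_graphs = frozen
        x_final = pool_and_fuse(stream_outputs)
        return classify(x_final, self.head_W, self.head_b)

    @property
    def scan_step_count(self) -> int:
        return 0 if self.stack is None else self.stack.scan_step_count

    def reset_scan_counter(self) -> None:
        if self.stack is not None:
            self.stack.reset_scan_counter()

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))
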