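"""Bimodal spatial graph priors over EEG channels.

Channels are graph nodes. Per temporal scale k a learnable transform maps the
batch-averaged feature tensor to one feature vector per channel; a *global*
adjacency connects channel pairs that are both strongly correlated (Pearson
correlation above its 75th off-diagonal percentile) and close in feature space
(Manhattan distance below its 25th off-diagonal percentile), weighted by a
Gaussian kernel of the Euclidean distance with a data-driven bandwidth
sigma = (mu_d + sd_d)/2. A *local* adjacency keeps only same-region pairs of
the global graph (anatomical scalp-region prior). Both graphs are duplicated
and stacked along a leading axis of size 2, giving the shallow and deep graph
encoders independently mutable copies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RegionMap", "TransformParams", "GraphPair",
    "batch_average", "node_features", "pairwise_stats",
    "global_graph", "local_graph", "stack_priors", "build_graph_pair",
    "export_edge_list",
]

PCC_GUARD = 1e-6  # added to the std denominator; constant rows stay finite


@dataclass(frozen=True)
class RegionMap:
    """Channel label -> scalp region id (contiguous ints starting at 0)."""

    mapping: dict[str, int]
    name: str = "custom"

    def __post_init__(self):
        ids = sorted(set(self.mapping.values()))
        if ids != list(range(len(ids))):
            raise ValueError("region ids must be contiguous starting at 0")

    @property
    def n_regions(self) -> int:
        return len(set(self.mapping.values()))

    def region_ids(self, channel_labels: list[str]) -> np.ndarray:
        missing = [ch for ch in channel_labels if ch not in self.mapping]
        if missing:
            raise KeyError(f"channels not in region map {self.name!r}: {missing}")
        return np.array([self.mapping[ch] for ch in channel_labels])

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionMap":
        path = Path(path)
        return cls(mapping=json.loads(path.read_text()), name=path.stem)

    @classmethod
    def from_ids(cls, region_ids, channel_labels=None, name="custom") -> "RegionMap":
        region_ids = list(region_ids)
        if channel_labels is None:
            channel_labels = [f"CH{i + 1:02d}" for i in range(len(region_ids))]
        return cls(dict(zip(channel_labels, map(int, region_ids))), name=name)


@dataclass
class TransformParams:
    """Learnable transform of the batch-averaged features: Z' = Z W + V with
    W (f*n_k x n_k) Xavier-uniform and V (c x n_k) zeros at init."""

    W: np.ndarray
    V: np.ndarray

    @classmethod
    def init(cls, c: int, n_k: int, f: int, rng: np.random.Generator) -> "TransformParams":
        limit = np.sqrt(6.0 / (f * n_k + n_k))
        return cls(W=rng.uniform(-limit, limit, size=(f * n_k, n_k)),
                   V=np.zeros((c, n_k)))


@dataclass
class GraphPair:
    W_global: np.ndarray
    W_local: np.ndarray
    G_global: np.ndarray          # (2, c, c) stacked duplicates
    G_local: np.ndarray
    scale_index: int = 0
    diagnostics: dict = field(default_factory=dict)


def batch_average(values: np.ndarray) -> np.ndarray:
    """Mean of the (b, n_k, c, f) feature tensor over the batch axis."""
    values = np.asarray(values)
    if values.shape[0] < 1:
        raise ValueError("empty batch")
    return values.mean(axis=0)


def flatten_node_matrix(avg: np.ndarray) -> np.ndarray:
    """(n_k, c, f) -> Z (c, f*n_k), sequence-major / band-minor flattening."""
    n_k, c, f = avg.shape
    return np.transpose(avg, (1, 0, 2)).reshape(c, n_k * f)


def node_features(avg: np.ndarray, params: TransformParams) -> np.ndarray:
    """Apply the learnable transform: Z' = Z W + V, one row per channel."""
    Z = flatten_node_matrix(np.asarray(avg))
    if Z.shape[1] != params.W.shape[0] or params.V.shape[0] != Z.shape[0]:
        raise ValueError(
            f"transform shape mismatch: Z {Z.shape}, W {params.W.shape}, "
            f"V {params.V.shape}")
    return Z @ params.W + params.V


def pairwise_stats(Zp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson correlation (guarded), Manhattan and Euclidean distance
    matrices between node feature rows."""
    Zp = np.asarray(Zp, dtype=np.float64)
    c = Zp.shape[0]
    if c < 2:
        raise ValueError("need at least 2 channels")
    centered = Zp - Zp.mean(axis=1, keepdims=True)
    std = Zp.std(axis=1, keepdims=True)
    normed = centered / (std + PCC_GUARD)
    kappa = (normed @ normed.T) / Zp.shape[1]
    diff = Zp[:, None, :] - Zp[None, :, :]
    manhattan = np.abs(diff).sum(axis=-1)
    euclid = np.sqrt((diff**2).sum(axis=-1))
    return kappa, manhattan, euclid


def _offdiag_upper(mat: np.ndarray) -> np.ndarray:
    c = mat.shape[0]
    iu = np.triu_indices(c, k=1)
    return mat[iu]


def graph_thresholds(kappa: np.ndarray, manhattan: np.ndarray,
                     euclid: np.ndarray) -> tuple[float, float, float]:
    """Data-driven gate thresholds and kernel bandwidth, computed over
    off-diagonal (upper-triangle) pairs only."""
    kappa_theta = float(np.percentile(_offdiag_upper(kappa), 75))
    d_theta = float(np.percentile(_offdiag_upper(manhattan), 25))
    e = _offdiag_upper(euclid)
    sigma = float((e.mean() + e.std()) / 2.0)
    return kappa_theta, d_theta, sigma


def global_graph(Zp: np.ndarray) -> tuple[np.ndarray, dict]:
    """Hybrid PCC + Manhattan-gated Gaussian-kernel adjacency.

    w_ij = exp(-||u_i - u_j||_2^2 / (2 sigma^2)) where kappa_ij >= kappa_theta
    and d_ij <= d_theta, else 0; diagonal fixed to 1. Returns the adjacency
    and a diagnostics dict (kappa, distances, sigma, thresholds, gate mask).
    """
    kappa, manhattan, euclid = pairwise_stats(Zp)
    kappa_theta, d_theta, sigma = graph_thresholds(kappa, manhattan, euclid)
    gate = (kappa >= kappa_theta) & (manhattan <= d_theta)
    with np.errstate(divide="ignore"):
        kernel = np.exp(-(euclid**2) / (2.0 * sigma**2)) if sigma > 0 else \
            (euclid == 0).astype(float)
    W = np.where(gate, kernel, 0.0)
    np.fill_diagonal(W, 1.0)
    W = np.minimum(W, W.T)  # gate is symmetric in exact arithmetic; enforce
    diagnostics = {"kappa": kappa, "manhattan": manhattan, "euclid": euclid,
                   "sigma": sigma, "kappa_theta": kappa_theta, "d_theta": d_theta,
                   "gate": gate}
    return W, diagnostics


def local_graph(W_global: np.ndarray, region_ids: np.ndarray) -> np.ndarray:
    """Mask the global adjacency to same-region channel pairs (diagonal kept)."""
    region_ids = np.asarray(region_ids)
    if region_ids.shape[0] != W_global.shape[0]:
        raise ValueError("region ids must cover every channel")
    same = region_ids[:, None] == region_ids[None, :]
    return np.where(same, W_global, 0.0)


def stack_priors(W_global: np.ndarray, W_local: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate each adjacency along a new leading axis -> (2, c, c); the two
    slices are independent copies (shallow vs deep encoders may diverge)."""
    G_global = np.stack([W_global.copy(), W_global.copy()])
    G_local = np.stack([W_local.copy(), W_local.copy()])
    return G_global, G_local


def build_graph_pair(values: np.ndarray, params: TransformParams,
                     region_ids: np.ndarray, scale_index: int = 0) -> GraphPair:
    """Full per-scale prior construction from a (b, n_k, c, f) tensor."""
    Zp = node_features(batch_average(values), params)
    W_g, diagnostics = global_graph(Zp)
    W_l = local_graph(W_g, region_ids)
    G_g, G_l = stack_priors(W_g, W_l)
    return GraphPair(W_global=W_g, W_local=W_l, G_global=G_g, G_local=G_l,
                     scale_index=scale_index, diagnostics=diagnostics)


def export_edge_list(W: np.ndarray, channel_labels: list[str],
                     path: str | Path) -> None:
    """Write the symmetric adjacency as an edge-list CSV (ch_i, ch_j, weight),
    upper triangle, nonzero entries only (connectivity-plot friendly)."""
    lines = ["ch_i,ch_j,weight"]
    c = W.shape[0]
    for i in range(c):
        for j in range(i + 1, c):
            if W[i, j] != 0:
                lines.append(f"{channel_labels[i]},{channel_labels[j]},{W[i, j]:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
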