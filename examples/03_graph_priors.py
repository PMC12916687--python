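"""Build the bimodal (global + local) spatial graph priors for one scale.

Node features come from a learnable transform of batch-averaged rPSD
tensors; pairs survive into the global graph only if their Pearson
correlation is above its 75th percentile AND their Manhattan distance below
its 25th percentile; surviving pairs get Gaussian-kernel weights. The local
graph keeps only same-region pairs."""

import numpy as np

from msgm import SegmentationConfig, SimConfig, generate_dataset
from msgm.features import build_feature_tensors, segment_first_level
from msgm.graphs import TransformParams, build_graph_pair

cfg = SimConfig(n_subjects=2, trials_per_subject=4, c=8, fs=128, duration_s=30,
                region_map=(0, 0, 0, 0, 1, 1, 1, 1), seed=0)
seg_cfg = SegmentationConfig(scales=((4, 2),))

segments = []
for rec in generate_dataset(cfg):
    segments += segment_first_level(rec.data, cfg.fs, seg_cfg)
values = build_feature_tensors(segments, cfg.fs, seg_cfg)[0].values
print("feature tensor:", values.shape)

rng = np.random.default_rng(0)
params = TransformParams.init(c=8, n_k=values.shape[1], f=7, rng=rng)
pair = build_graph_pair(values, params, np.asarray(cfg.region_map))

off = ~np.eye(8, dtype=bool)
print(f"global graph: {np.count_nonzero(pair.W_global[off]) // 2} edges "
      f"(of {8 * 7 // 2} possible), sigma={pair.diagnostics['sigma']:.3f}")
print(f"local graph:  {np.count_nonzero(pair.W_local[off]) // 2} edges "
      f"(same-region survivors only)")
print("stacked priors:", pair.G_global.shape, "- two independently mutable copies")
# The joint percentile gate keeps at most ~25% of pairs; the local graph is a
# subset of the global one restricted to the two simulated scalp regions.
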