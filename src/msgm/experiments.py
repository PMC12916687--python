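"""Canned synthetic-data experiments at the package's desk scale.

The desk-scale study conditions (8 subjects x 4 trials of 44 s, 16 channels
in 4 regions, fs = 128 Hz, two temporal scales (4 s, 2 s) and (8 s, 4 s),
alpha-band effect) are the ones shipped in ``configs/small.yaml``; they keep
a full leave-one-subject-out run on one CPU core in the minutes range while
leaving the classification task non-trivial (single-trial band SNR ~ 1,
per-subject gain jitter). The same conditions back the learnability and
ablation benchmarks reported by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .features import SegmentationConfig
from .model import ABLATION_FLAGS, ModelConfig
from .simulate import SimConfig, generate_dataset
from .training import (EvalReport, TrainConfig, make_folds, prepare_features,
                       train)

__all__ = ["desk_sim_config", "desk_segmentation", "run_loso_benchmark",
           "run_ablation_benchmark"]


def desk_sim_config(seed: int, effect_size: float = 1.0) -> SimConfig:
    return SimConfig(n_subjects=8, trials_per_subject=4, c=16, fs=128.0,
                     duration_s=44.0, effect_size=effect_size, seed=seed)


def desk_segmentation() -> SegmentationConfig:
    return SegmentationConfig(l_s=20.0, s_s=4.0, scales=((4.0, 2.0), (8.0, 4.0)))


def run_loso_benchmark(seed: int, effect_size: float = 1.0,
                       ablation: str | None = None,
                       epochs: int = 15) -> EvalReport:
    """Generate the desk-scale dataset and run the full LOSO evaluation."""
    sim = desk_sim_config(seed, effect_size)
    data = prepare_features(generate_dataset(sim), desk_segmentation())
    flags = {ablation: True} if ablation else {}
    cfg = ModelConfig(c=sim.c, n_k=data.n_k, d_out=len(data.class_names),
                      **flags)
    folds = make_folds(sorted(set(data.subjects)), "loso", seed=seed)
    return train(data, folds, cfg, np.asarray(sim.region_map),
                 TrainConfig(epochs=epochs, seed=seed))


def run_ablation_benchmark(seeds: tuple[int, ...] = (1, 2, 3),
                           flags: tuple[str, ...] = ABLATION_FLAGS,
                           effect_size: float = 1.0) -> dict[str, list[float]]:
    """Mean LOSO accuracy per variant (full model plus each single ablation)
    for every seed; same task and scale as the learnability benchmark."""
    results: dict[str, list[float]] = {"full": []}
    for flag in flags:
        results[flag] = []
    for seed in seeds:
        results["full"].append(
            run_loso_benchmark(seed, effect_size).mean_accuracy)
        for flag in flags:
            results[flag].append(
                run_loso_benchmark(seed, effect_size, ablation=flag).mean_accuracy)
    return results
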