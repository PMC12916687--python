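"""Schema-validated pipeline configuration (YAML/JSON).

Every default follows the published training recipe (AdamW at 3e-4, label
smoothing 0.1, dropout 0.25, batch 32, patience 5, h=32, one temporal block,
d_state=16, conv kernel 4, GCN depths [1, 2]); quantities the recipe leaves
open (second-level scales, Chebyshev order, encoder width) carry the
package's documented defaults. Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .features import SegmentationConfig
from .model import ModelConfig
from .simulate import SimConfig
from .training import TrainConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "dump_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSection(_Section):
    n_subjects: int = 8
    trials_per_subject: int = 6
    c: int = 16
    fs: float = 128.0
    duration_s: float = 60.0
    classes: list[str] = Field(default_factory=lambda: ["low", "high"])
    effect_band: str = "alpha"
    effect_size: float = 1.0
    n_regions: int = 4
    within_region_corr: float = 0.6
    noise_exponent: float = 1.0

    def to_sim_config(self, seed: int) -> SimConfig:
        n_regions = min(self.n_regions, self.c)
        region_map = tuple(int(i * n_regions // self.c) for i in range(self.c))
        return SimConfig(
            n_subjects=self.n_subjects, trials_per_subject=self.trials_per_subject,
            c=self.c, fs=self.fs, duration_s=self.duration_s,
            classes=tuple(self.classes), effect_band=self.effect_band,
            effect_size=self.effect_size, region_map=region_map,
            within_region_corr=self.within_region_corr,
            noise_exponent=self.noise_exponent, seed=seed)


class SegmentationSection(_Section):
    window_s: float = 20.0
    hop_s: float = 4.0
    scales: list[list[float]] = Field(
        default_factory=lambda: [[4.0, 2.0], [8.0, 4.0], [12.0, 6.0]])

    def to_segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            l_s=self.window_s, s_s=self.hop_s,
            scales=tuple(tuple(s) for s in self.scales))

    @model_validator(mode="after")
    def _validate(self):
        self.to_segmentation_config()  # raises on hop > window etc.
        return self


class ModelSection(_Section):
    h: int = 32
    M: int = 1
    cheb_order: int = 3
    gcn_depths: list[int] = Field(default_factory=lambda: [1, 2])
    w_out: int = 8
    d_state: int = 16
    conv_kernel: int = 4
    expansion: int = 2
    dropout: float = 0.25
    feature_type: str = "rpsd"
    region_partition: str = "default"
    share_streams: bool = True


class TrainingSection(_Section):
    lr: float = 3e-4
    weight_decay: float = 0.01
    label_smoothing: float = 0.1
    batch_size: int = 32
    epochs: int = 20
    patience: int = 5
    protocol: str = "loso"
    leave_n: int | None = None

    def to_train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                           label_smoothing=self.label_smoothing,
                           batch_size=self.batch_size, epochs=self.epochs,
                           patience=self.patience, seed=seed)


class PipelineConfig(_Section):
    seed: int = 0
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)

    def model_config_for(self, c: int, n_k: tuple[int, ...], d_out: int,
                         **ablation_flags) -> ModelConfig:
        m = self.model
        return ModelConfig(
            c=c, f=7, n_k=n_k, d_out=d_out, h=m.h, M=m.M,
            cheb_order=m.cheb_order, gcn_depths=tuple(m.gcn_depths),
            w_out=m.w_out, d_state=m.d_state, conv_kernel=m.conv_kernel,
            expansion=m.expansion, dropout=m.dropout,
            feature_type=m.feature_type, share_streams=m.share_streams,
            **ablation_flags)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON config; an empty or absent file yields full defaults."""
    if path is None:
        return PipelineConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    cfg = PipelineConfig.model_validate(data)
    logger.debug("loaded config %s (hash %s)", path, config_hash(cfg))
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash stamped onto every artifact the pipeline writes."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
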