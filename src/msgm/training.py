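"""Subject-independent training and evaluation.

Protocols: leave-one-subject-out (LOSO; one fold per subject, remaining
subjects split 8:2 into train/validation *by subject*) and leave-n-subject-out
(ceil(S/n) folds, 9:1 split). Segments inherit their trial's label and every
metric is computed at segment level; subjects never straddle the
train/validation/test boundary, which is asserted when folds are built.

Model selection follows the published recipe: cross-entropy with label
smoothing 0.1, AdamW at 3e-4, batch size 32, early stopping with patience 5
on validation accuracy, best-validation checkpoint evaluated on the held-out
subjects. Welch's t-test (Welch-Satterthwaite degrees of freedom, two-sided
p) and Cohen's d compare per-fold accuracy lists or published (mean, sd, n)
summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats
from sklearn.metrics import f1_score

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .features import DEFAULT_BANDS, BandTable, SegmentationConfig, \
    build_feature_tensors, compute_rpsd, segment_first_level
from .model import ABLATION_FLAGS, ModelConfig, MSGMModel
from .nn import AdamW
from .simulate import RawRecording

__all__ = [
    "FoldPlan", "Fold", "EvalReport", "TrainConfig", "WelchResult",
    "binarize_valence", "make_folds", "welch_stats", "prepare_features",
    "train", "train_fold",
]


# -- labels -------------------------------------------------------------------

def binarize_valence(score: float) -> str | None:
    """Valence score -> 'high' (> 3.0) or 'low' (< 3.0); scores exactly at
    the 3.0 threshold are excluded (returns None with a warning)."""
    score = float(score)
    if score > 3.0:
        return "high"
    if score < 3.0:
        return "low"
    warnings.warn("valence score exactly at the 3.0 threshold: trial excluded",
                  UserWarning, stacklevel=2)
    return None


# -- folds --------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    test_subjects: tuple[int, ...]
    train_subjects: tuple[int, ...]
    val_subjects: tuple[int, ...]


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]
    protocol: str
    seed: int

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_folds(subject_ids: Sequence[int], protocol: str = "loso", *,
               n: int | None = None, seed: int = 0) -> FoldPlan:
    """Build a subject-disjoint cross-validation plan.

    ``loso``: one fold per subject; the remaining subjects are shuffled and
    split 8:2 into train/validation. ``leave_n_out``: ceil(S/n) folds of n
    test subjects each (the last may be smaller), remaining split 9:1.
    """
    subjects = sorted(set(int(s) for s in subject_ids))
    S = len(subjects)
    if S < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    folds: list[Fold] = []
    if protocol == "loso":
        test_groups = [[s] for s in subjects]
        val_frac = 0.2
    elif protocol == "leave_n_out":
        if n is None or not 1 <= n < S:
            raise ValueError(f"leave_n_out requires 1 <= n < {S}")
        order = list(rng.permutation(subjects))
        test_groups = [order[i:i + n] for i in range(0, S, n)]
        val_frac = 0.1
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    for test in test_groups:
        rest = [s for s in subjects if s not in test]
        rest = list(rng.permutation(rest))
        n_val = max(1, round(val_frac * len(rest)))
        val = rest[:n_val]
        tr = rest[n_val:]
        fold = Fold(tuple(sorted(test)), tuple(sorted(tr)), tuple(sorted(val)))
        assert not (set(fold.test_subjects) & set(fold.train_subjects)
                    | set(fold.test_subjects) & set(fold.val_subjects))
        folds.append(fold)
    covered = sorted(s for f in folds for s in f.test_subjects)
    assert covered == subjects, "every subject must be tested exactly once"
    return FoldPlan(tuple(folds), protocol, seed)


# -- Welch statistics ---------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    delta: float
    t: float
    p: float
    df: float
    d: float


def _summarize(x) -> tuple[float, float, int]:
    if isinstance(x, tuple) and len(x) == 3:
        mean, sd, n = x
        return float(mean), float(sd), int(n)
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 observations per group")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def welch_stats(acc_a, acc_b) -> WelchResult:
    """Welch's t-test and Cohen's d between two accuracy samples.

    Each argument is either a per-fold list/array or a (mean, sd, n) summary
    tuple. t = (m_a - m_b)/sqrt(s_a^2/n_a + s_b^2/n_b); df by
    Welch-Satterthwaite; two-sided p; d = (m_a - m_b)/sqrt((s_a^2+s_b^2)/2).
    """
    m_a, s_a, n_a = _summarize(acc_a)
    m_b, s_b, n_b = _summarize(acc_b)
    if min(n_a, n_b) < 2 or s_a < 0 or s_b < 0:
        raise ValueError("need n >= 2 and nonnegative SDs")
    delta = m_a - m_b
    va, vb = s_a**2 / n_a, s_b**2 / n_b
    if va + vb == 0:
        t = math.inf if delta > 0 else (-math.inf if delta < 0 else 0.0)
        warnings.warn("zero pooled variance: t is infinite" if delta != 0
                      else "degenerate groups", RuntimeWarning, stacklevel=2)
        return WelchResult(delta, t, 0.0 if delta != 0 else 1.0, math.nan,
                           math.inf if delta > 0 else (-math.inf if delta else 0.0))
    t = delta / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    d = delta / math.sqrt((s_a**2 + s_b**2) / 2.0)
    return WelchResult(delta, t, p, df, d)


# -- data preparation ---------------------------------------------------------

@dataclass
class SegmentDataset:
    """Featurized first-level segments: one (B, n_k, c, f) array per scale."""

    features: list[np.ndarray]
    labels: np.ndarray          # (B,) int class index
    subjects: np.ndarray        # (B,)
    class_names: list[str]
    n_k: tuple[int, ...]
    c: int

    def subset(self, subject_set) -> "SegmentDataset":
        mask = np.isin(self.subjects, list(subject_set))
        return SegmentDataset([f[mask] for f in self.features],
                              self.labels[mask], self.subjects[mask],
                              self.class_names, self.n_k, self.c)

    def __len__(self):
        return self.labels.size


def prepare_features(recordings: Sequence[RawRecording],
                     seg_cfg: SegmentationConfig,
                     bands: BandTable = DEFAULT_BANDS,
                     feature_type: str = "rpsd") -> SegmentDataset:
    """Slice every recording at the first level and featurize all segments.

    ``feature_type``: 'rpsd' (relative, the default), 'psd' (absolute band
    power) or 'de' (differential entropy, 0.5*log(2*pi*e*power))."""
    segs, labels, subjects = [], [], []
    class_names = sorted({str(r.label) for r in recordings})
    for rec in recordings:
        for seg in segment_first_level(rec.data, rec.fs, seg_cfg):
            segs.append(seg)
            labels.append(class_names.index(str(rec.label)))
            subjects.append(rec.subject_id)
    fs = recordings[0].fs
    relative = feature_type == "rpsd"
    tensors = build_feature_tensors(segs, fs, seg_cfg, bands, relative=relative)
    features = []
    for ft in tensors:
        vals = ft.values
        if feature_type == "de":
            vals = 0.5 * np.log(2 * np.pi * np.e * np.maximum(vals, 1e-12))
        features.append(vals)
    return SegmentDataset(features, np.asarray(labels), np.asarray(subjects),
                          class_names, tuple(f.shape[1] for f in features),
                          features[0].shape[2])


# -- training loop ------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    lr: float = 3e-4
    weight_decay: float = 0.01
    label_smoothing: float = 0.1
    batch_size: int = 32
    epochs: int = 20
    patience: int = 5
    seed: int = 0


@dataclass
class FoldResult:
    accuracy: float          # percent
    f1: float                # percent, macro
    n_test: int
    epochs_run: int
    best_val_accuracy: float


@dataclass
class EvalReport:
    fold_results: list[FoldResult] = field(default_factory=list)
    protocol: str = "loso"

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.fold_results])

    @property
    def f1s(self) -> np.ndarray:
        return np.array([f.f1 for f in self.fold_results])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.fold_results) > 1 else 0.0

    @property
    def mean_f1(self) -> float:
        return float(self.f1s.mean())

    def summary(self) -> str:
        return (f"{self.protocol}: accuracy {self.mean_accuracy:.2f} "
                f"± {self.sd_accuracy:.2f} %, macro-F1 {self.mean_f1:.2f} % "
                f"over {len(self.fold_results)} folds")


def _smoothed_cross_entropy(logits: Tensor, targets: np.ndarray,
                            smoothing: float) -> Tensor:
    b, d = logits.shape
    q = np.full((b, d), smoothing / d)
    q[np.arange(b), targets] += 1.0 - smoothing
    logp = ad.log_softmax(logits, axis=-1)
    return (Tensor(q) * logp).sum() * (-1.0 / b)


def _evaluate(model: MSGMModel, data: SegmentDataset,
              batch_size: int) -> tuple[float, float]:
    model.eval()
    preds = []
    with no_grad():
        for start in range(0, len(data), batch_size):
            batch = [f[start:start + batch_size] for f in data.features]
            logits = model(batch)
            preds.append(np.argmax(logits.data, axis=1))
    model.train()
    pred = np.concatenate(preds)
    acc = 100.0 * float(np.mean(pred == data.labels))
    f1 = 100.0 * float(f1_score(data.labels, pred, average="macro",
                                zero_division=0))
    return acc, f1


def _select_scales(data: SegmentDataset, cfg: ModelConfig) -> SegmentDataset:
    if not cfg.no_temporal_multiscale or len(data.n_k) == 1:
        return data
    keep = int(np.argmin(data.n_k))  # longest window = fewest tokens
    return SegmentDataset([data.features[keep]], data.labels, data.subjects,
                          data.class_names, (data.n_k[keep],), data.c)


def save_checkpoint(model: MSGMModel, path) -> None:
    """Persist the model state as an .npz array container plus a JSON sidecar
    with the architectural config (enough to rebuild and reload)."""
    import dataclasses
    import json
    from pathlib import Path
    path = Path(path)
    state = model.state_dict()
    graphs = {}
    if model.frozen_graphs is not None:
        for k, g in enumerate(model.frozen_graphs):
            graphs[f"graph_global_{k}"] = g["W_global"]
            graphs[f"graph_local_{k}"] = g["W_local"]
    np.savez(path, **state, **graphs,
             __region_ids__=model.region_ids)
    meta = dataclasses.asdict(model.cfg)
    meta["n_scales_frozen"] = len(model.frozen_graphs or [])
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path) -> MSGMModel:
    import json
    from pathlib import Path
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n_scales = meta.pop("n_scales_frozen")
    for key in ("n_k", "gcn_depths"):
        meta[key] = tuple(meta[key])
    cfg = ModelConfig(**meta)
    with np.load(path) as z:
        region_ids = z["__region_ids__"]
        model = MSGMModel(cfg, region_ids, np.random.default_rng(0))
        model.load_state_dict({k: z[k] for k, _ in model.named_parameters()})
        if n_scales:
            model.frozen_graphs = [
                {"W_global": z[f"graph_global_{k}"],
                 "W_local": z[f"graph_local_{k}"], "diagnostics": {}}
                for k in range(n_scales)]
    return model


def train_fold(data: SegmentDataset, fold: Fold, model_cfg: ModelConfig,
               region_ids: np.ndarray, train_cfg: TrainConfig,
               fold_index: int = 0, checkpoint_path=None) -> FoldResult:
    """Train one fold from a fresh initialization and score the held-out
    subjects with the best-validation checkpoint."""
    data = _select_scales(data, model_cfg)
    tr = data.subset(fold.train_subjects)
    va = data.subset(fold.val_subjects)
    te = data.subset(fold.test_subjects)
    rng = np.random.default_rng([train_cfg.seed, 3, fold_index])
    model = MSGMModel(model_cfg, region_ids, rng)
    opt = AdamW(model.parameters(), lr=train_cfg.lr,
                weight_decay=train_cfg.weight_decay)
    best_val, best_state, best_graphs, patience_left = -1.0, None, None, train_cfg.patience
    epochs_run = 0
    for epoch in range(train_cfg.epochs):
        epochs_run = epoch + 1
        order = rng.permutation(len(tr))
        for start in range(0, len(tr), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            if idx.size < 2:
                continue
            batch = [f[idx] for f in tr.features]
            targets = tr.labels[idx]
            logits = model(batch, rng)
            loss = _smoothed_cross_entropy(logits, targets,
                                           train_cfg.label_smoothing)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, fold {fold_index}")
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_acc, _ = _evaluate(model, va, train_cfg.batch_size)
        if val_acc >= best_val:
            # checkpoint the highest validation accuracy; ties resolve to the
            # later (longer-trained) epoch
            best_state = model.state_dict()
            best_graphs = [dict(g) for g in model.frozen_graphs]
        if val_acc > best_val:
            best_val = val_acc
            patience_left = train_cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.load_state_dict(best_state)
    model.frozen_graphs = best_graphs
    acc, f1 = _evaluate(model, te, train_cfg.batch_size)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return FoldResult(accuracy=acc, f1=f1, n_test=len(te),
                      epochs_run=epochs_run, best_val_accuracy=best_val)


def train(data: SegmentDataset, folds: FoldPlan, model_cfg: ModelConfig,
          region_ids: np.ndarray, train_cfg: TrainConfig,
          checkpoint_dir=None) -> EvalReport:
    """Run every fold of the plan; deterministic given the seeds."""
    from pathlib import Path
    report = EvalReport(protocol=folds.protocol)
    for i, fold in enumerate(folds):
        ckpt = None
        if checkpoint_dir is not None:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            ckpt = Path(checkpoint_dir) / f"fold{i:02d}.npz"
        report.fold_results.append(
            train_fold(data, fold, model_cfg, region_ids, train_cfg, i,
                       checkpoint_path=ckpt))
    return report
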