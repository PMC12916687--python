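"""Two-level multi-scale segmentation and 7-band relative-PSD features.

An EEG trial (channels x samples) is first cut into long overlapping windows
(default 20 s with a 4 s hop), and each window is then re-cut at several finer
scales (window length l'_k, hop s'_k). Every sub-segment is summarized per
channel by the relative power spectral density (rPSD) in seven canonical
frequency bands: delta 1-4, theta 4-8, alpha 8-12, low-beta 12-16, beta 16-20,
high-beta 20-28 and gamma 30-45 Hz. Relative (rather than absolute) band power
is scale-invariant, which makes the features robust to per-subject amplitude
differences (skull thickness, electrode impedance).

Per scale k the features form a tensor of shape (b, n_k, c, 7): b first-level
segments, n_k sub-segments, c channels, 7 bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "Band",
    "BandTable",
    "DEFAULT_BANDS",
    "SegmentationConfig",
    "FeatureTensor",
    "segment_first_level",
    "segment_second_level",
    "compute_rpsd",
    "build_feature_tensors",
]


@dataclass(frozen=True)
class Band:
    name: str
    f_lo: float
    f_hi: float


class BandTable:
    """Ordered, non-overlapping frequency bands; power is integrated on
    [f_lo, f_hi) and normalized by the power over the union of all bands."""

    def __init__(self, bands: Sequence[Band]):
        bands = list(bands)
        for band in bands:
            if not band.f_lo < band.f_hi:
                raise ValueError(f"band {band.name}: f_lo must be < f_hi")
        for a, b in zip(bands, bands[1:]):
            if b.f_lo < a.f_hi:
                raise ValueError(f"bands {a.name} and {b.name} overlap")
        self.bands = bands

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def top_edge(self) -> float:
        return max(b.f_hi for b in self.bands)

    def masks(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean (n_bands, n_freqs) selecting each band's bins."""
        return np.stack([(freqs >= b.f_lo) & (freqs < b.f_hi) for b in self.bands])


DEFAULT_BANDS = BandTable([
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("low_beta", 12.0, 16.0),
    Band("beta", 16.0, 20.0),
    Band("high_beta", 20.0, 28.0),
    Band("gamma", 30.0, 45.0),
])


@dataclass(frozen=True)
class SegmentationConfig:
    """First-level window (l_s, s_s in seconds) and the list of second-level
    scales [(l'_k, s'_k), ...]."""

    l_s: float = 20.0
    s_s: float = 4.0
    scales: tuple[tuple[float, float], ...] = ((4.0, 2.0), (8.0, 4.0), (12.0, 6.0))

    def __post_init__(self):
        if not 0 < self.s_s <= self.l_s:
            raise ValueError("first level: need 0 < hop <= window")
        if len(self.scales) < 1:
            raise ValueError("need at least one second-level scale")
        for lk, sk in self.scales:
            if not 0 < sk <= lk <= self.l_s:
                raise ValueError(
                    f"scale ({lk}, {sk}): need 0 < hop <= window <= {self.l_s}")

    @property
    def n_scales(self) -> int:
        return len(self.scales)


@dataclass
class FeatureTensor:
    """Per-scale rPSD tensor of shape (b, n_k, c, f)."""

    values: np.ndarray
    scale: tuple[float, float]
    scale_index: int
    band_names: list[str] = field(default_factory=lambda: DEFAULT_BANDS.names)
    subject_ids: np.ndarray | None = None   # (b,)
    trial_ids: np.ndarray | None = None     # (b,)
    segment_ids: np.ndarray | None = None   # (b,) first-level segment index
    labels: np.ndarray | None = None        # (b,)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def _n_windows(total: int, win: int, hop: int) -> int:
    return (total - win) // hop + 1


def segment_first_level(data: np.ndarray, fs: float,
                        cfg: SegmentationConfig) -> list[np.ndarray]:
    """Slice a (c, L) recording into overlapping first-level windows.

    Returns floor((L - l*fs)/(s*fs)) + 1 segments of shape (c, l*fs); the
    trailing remainder is discarded.
    """
    data = np.asarray(data)
    win = int(round(cfg.l_s * fs))
    hop = int(round(cfg.s_s * fs))
    L = data.shape[-1]
    if L < win:
        raise ValueError(
            f"recording too short for first-level window: requires {win} samples "
            f"({cfg.l_s} s at fs={fs}), got {L}")
    count = _n_windows(L, win, hop)
    return [data[:, i * hop:i * hop + win] for i in range(count)]


def segment_second_level(segment: np.ndarray, scale: tuple[float, float],
                         fs: float) -> list[np.ndarray]:
    """Slice one first-level segment at a finer scale (l'_k, s'_k)."""
    lk, sk = scale
    win = int(round(lk * fs))
    hop = int(round(sk * fs))
    L = segment.shape[-1]
    if win > L:
        raise ValueError(
            f"second-level window {lk} s ({win} samples) exceeds segment "
            f"length {L} samples")
    count = _n_windows(L, win, hop)
    return [segment[:, i * hop:i * hop + win] for i in range(count)]


def welch_psd(x: np.ndarray, fs: float, nperseg: int | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch spectrum over the last axis: Hann window, 50% overlap, mean
    averaging, per-window length min(2 s * fs, T)."""
    T = x.shape[-1]
    if nperseg is None:
        nperseg = min(int(round(2 * fs)), T)
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, average="mean", axis=-1)


def compute_rpsd(subsegment: np.ndarray, fs: float,
                 bands: BandTable = DEFAULT_BANDS, *,
                 relative: bool = True) -> np.ndarray:
    """rPSD feature matrix for one sub-segment.

    Parameters
    ----------
    subsegment : (..., c, T) array. The Welch spectrum is taken over the last
        axis; leading axes are carried through, so whole batches of
        sub-segments can be featurized in one call.
    relative : normalize each channel's band powers by the total power over
        the union of band supports (rows then sum to 1). With
        ``relative=False`` raw band powers are returned (absolute-PSD
        ablation).

    Returns an array of band powers with shape (..., c, n_bands). Zero-variance
    channels yield a zero row (guarded division) and a warning.
    """
    if fs <= 2 * bands.top_edge:
        raise ValueError(
            f"sampling rate {fs} Hz too low for top band edge {bands.top_edge} Hz")
    freqs, psd = welch_psd(np.asarray(subsegment, dtype=np.float64), fs)
    masks = bands.masks(freqs)                       # (f, n_freqs)
    df = freqs[1] - freqs[0]
    band_power = psd @ (masks.T * df)                # (..., c, f)
    if not relative:
        return band_power
    total = band_power.sum(axis=-1, keepdims=True)
    zero = total[..., 0] <= 0
    if np.any(zero):
        warnings.warn("zero-variance channel(s) produced an all-zero rPSD row",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rpsd = np.where(total > 0, band_power / np.where(total > 0, total, 1.0), 0.0)
    return rpsd


def build_feature_tensors(segments: Sequence[np.ndarray], fs: float,
                          cfg: SegmentationConfig,
                          bands: BandTable = DEFAULT_BANDS, *,
                          relative: bool = True,
                          subject_ids: np.ndarray | None = None,
                          trial_ids: np.ndarray | None = None,
                          segment_ids: np.ndarray | None = None,
                          labels: np.ndarray | None = None,
                          ) -> list[FeatureTensor]:
    """Featurize a batch of first-level segments at every configured scale.

    All segments must share the channel count; the result is one
    FeatureTensor of shape (b, n_k, c, f) per scale k.
    """
    segments = [np.asarray(s) for s in segments]
    if not segments:
        raise ValueError("empty segment batch")
    c = segments[0].shape[0]
    if any(s.shape[0] != c for s in segments):
        raise ValueError("segments have heterogeneous channel counts")
    batch = np.stack(segments)                       # (b, c, L)
    out: list[FeatureTensor] = []
    for k, scale in enumerate(cfg.scales):
        lk, sk = scale
        win = int(round(lk * fs))
        hop = int(round(sk * fs))
        L = batch.shape[-1]
        if win > L:
            raise ValueError(f"scale {scale} window exceeds segment length")
        n_k = _n_windows(L, win, hop)
        # (b, n_k, c, win) view of all sub-segments, then one Welch call
        idx = np.arange(n_k)[:, None] * hop + np.arange(win)[None, :]
        subs = batch[:, :, idx]                      # (b, c, n_k, win)
        subs = np.swapaxes(subs, 1, 2)               # (b, n_k, c, win)
        values = compute_rpsd(subs, fs, bands, relative=relative)
        out.append(FeatureTensor(
            values=values, scale=scale, scale_index=k, band_names=bands.names,
            subject_ids=subject_ids, trial_ids=trial_ids,
            segment_ids=segment_ids, labels=labels))
    return out
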