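"""Synthetic multichannel EEG with class-dependent band-power structure.

The generator emulates the statistics the downstream pipeline assumes of real
emotion-EEG corpora without requiring any licensed recordings:

* each scalp region carries one latent sinusoidal oscillator per frequency
  band (random frequency inside the band, random phase), shared by all
  channels of the region;
* every channel adds 1/f^alpha background noise, mixed from a region-shared
  and a private stream so that within-region channels correlate;
* one class ("boosted" = the last entry of ``classes``) has the amplitude of
  the oscillator in ``effect_band`` scaled by (1 + effect_size) — band power
  therefore differs by the factor (1 + effect_size)^2 in that band only;
* each subject draws a global multiplicative gain and mild per-band gain
  jitter once, emulating skull-thickness/impedance variability and making
  leave-one-subject-out evaluation non-trivial.

Oscillator amplitudes are calibrated so that the single-trial band SNR
(oscillator band power over noise band power) is ~1 in every band: the
classification task is learnable but not trivial.

Everything is deterministic given (seed, subject_id, trial_id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import DEFAULT_BANDS, BandTable

__all__ = ["SimConfig", "RawRecording", "generate_recording", "generate_dataset"]

NOISE_STD_UV = 10.0  # total background-noise std per channel, microvolts
SUBJECT_GAIN_SIGMA = 0.15      # lognormal sigma of the per-subject global gain
SUBJECT_BAND_SIGMA = 0.10     # lognormal sigma of per-subject per-band jitter


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 8
    trials_per_subject: int = 6
    c: int = 16
    fs: float = 128.0
    duration_s: float = 60.0
    classes: tuple[str, ...] = ("low", "high")
    effect_band: str = "alpha"
    effect_size: float = 1.0
    region_map: tuple[int, ...] | None = None   # channel -> region id; default 4 blocks
    within_region_corr: float = 0.6
    noise_exponent: float = 1.0
    seed: int = 0
    bands: BandTable = field(default=DEFAULT_BANDS, repr=False)

    def __post_init__(self):
        if self.c < 2:
            raise ValueError("need at least 2 channels")
        if self.fs <= 2 * self.bands.top_edge:
            raise ValueError(
                f"fs={self.fs} too low: need > {2 * self.bands.top_edge} Hz for the "
                f"{self.bands.top_edge} Hz top band edge")
        if self.duration_s < 20.0:
            raise ValueError("duration_s must cover the 20 s first-level window")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.within_region_corr < 1:
            raise ValueError("within_region_corr must be in [0, 1)")
        if self.effect_band not in self.bands.names:
            raise ValueError(f"unknown effect band {self.effect_band!r}")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if self.region_map is None:
            n_regions = min(4, self.c)
            rmap = tuple(int(i * n_regions // self.c) for i in range(self.c))
            object.__setattr__(self, "region_map", rmap)
        if len(self.region_map) != self.c:
            raise ValueError("region_map length must equal channel count")

    @property
    def n_regions(self) -> int:
        return len(set(self.region_map))

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @property
    def channel_labels(self) -> list[str]:
        return [f"CH{i + 1:02d}" for i in range(self.c)]

    @property
    def boosted_class(self) -> str:
        return self.classes[-1]


@dataclass
class RawRecording:
    """One subject/trial EEG matrix (c x L, microvolts) with its metadata."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: int
    trial_id: int
    label: str | float
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN/Inf")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel label count mismatch")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")


def _noise_band_fractions(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """rFFT amplitude shaping for 1/f^alpha noise and the fraction of the
    noise variance that falls into each band."""
    freqs = np.fft.rfftfreq(cfg.n_samples, 1.0 / cfg.fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-cfg.noise_exponent / 2.0)
    power = shaping**2
    masks = cfg.bands.masks(freqs)
    fractions = (masks * power).sum(axis=1) / power.sum()
    return shaping, fractions


def _oscillator_amplitudes(cfg: SimConfig) -> np.ndarray:
    """Per-band amplitudes giving single-trial band SNR ~= 1 (a^2/2 equals the
    noise power expected inside each band)."""
    _, fractions = _noise_band_fractions(cfg)
    band_noise_power = fractions * NOISE_STD_UV**2
    return np.sqrt(2.0 * band_noise_power)


def _colored_noise(rng: np.random.Generator, shaping: np.ndarray, n: int,
                   size: int) -> np.ndarray:
    """`size` rows of 1/f^alpha noise with total std NOISE_STD_UV each."""
    re = rng.standard_normal((size, shaping.size))
    im = rng.standard_normal((size, shaping.size))
    spec = (re + 1j * im) * shaping
    x = np.fft.irfft(spec, n=n, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x * (NOISE_STD_UV / std)


def _subject_params(cfg: SimConfig, subject_id: int) -> tuple[float, np.ndarray]:
    rng = np.random.default_rng([cfg.seed, 1, int(subject_id)])
    gain = float(np.exp(rng.normal(0.0, SUBJECT_GAIN_SIGMA)))
    band_gain = np.exp(rng.normal(0.0, SUBJECT_BAND_SIGMA, size=len(cfg.bands)))
    return gain, band_gain


def generate_recording(cfg: SimConfig, subject_id: int, trial_id: int,
                       label: str) -> RawRecording:
    """Generate one labeled trial; bitwise deterministic given
    (cfg.seed, subject_id, trial_id)."""
    if label not in cfg.classes:
        raise ValueError(f"label {label!r} not in classes {cfg.classes}")
    rng = np.random.default_rng([cfg.seed, 2, int(subject_id), int(trial_id)])
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    shaping, _ = _noise_band_fractions(cfg)
    amps = _oscillator_amplitudes(cfg)
    subj_gain, subj_band_gain = _subject_params(cfg, subject_id)
    regions = np.asarray(cfg.region_map)
    region_ids = np.unique(regions)
    n_bands = len(cfg.bands)
    eff_idx = cfg.bands.index(cfg.effect_band)

    # latent oscillators: one (freq, phase) per (region, band), shared in-region
    freqs = np.empty((len(region_ids), n_bands))
    phases = rng.uniform(0, 2 * np.pi, size=(len(region_ids), n_bands))
    for j, band in enumerate(cfg.bands):
        margin = 0.1 * (band.f_hi - band.f_lo)
        freqs[:, j] = rng.uniform(band.f_lo + margin, band.f_hi - margin,
                                  size=len(region_ids))

    band_scale = amps * subj_band_gain
    if label == cfg.boosted_class:
        band_scale = band_scale.copy()
        band_scale[eff_idx] *= 1.0 + cfg.effect_size

    # oscillator + noise powers fix the noise-mixing weight that realizes the
    # requested total within-region correlation (clamped to [0, 1])
    osc_power = float(np.sum(band_scale**2) / 2.0)
    noise_power = NOISE_STD_UV**2
    total = osc_power + noise_power
    rho_noise = (cfg.within_region_corr * total - osc_power) / noise_power
    rho_noise = float(np.clip(rho_noise, 0.0, 1.0))

    region_noise = _colored_noise(rng, shaping, n, len(region_ids))
    private_noise = _colored_noise(rng, shaping, n, cfg.c)

    osc = np.zeros((len(region_ids), n))
    for r in range(len(region_ids)):
        osc[r] = (band_scale[None, :] * np.sin(
            2 * np.pi * freqs[r][:, None] * t[None, :] + phases[r][:, None]).T
        ).sum(axis=1)

    reg_index = np.searchsorted(region_ids, regions)
    data = (osc[reg_index]
            + np.sqrt(rho_noise) * region_noise[reg_index]
            + np.sqrt(1.0 - rho_noise) * private_noise)
    data *= subj_gain

    return RawRecording(
        data=data, fs=cfg.fs, channel_labels=cfg.channel_labels,
        subject_id=int(subject_id), trial_id=int(trial_id), label=label,
        info={"osc_freqs": freqs, "region_ids": region_ids,
              "subject_gain": subj_gain, "rho_noise": rho_noise})


def generate_dataset(cfg: SimConfig) -> list[RawRecording]:
    """All n_subjects x trials_per_subject recordings, labels balanced per
    subject (classes assigned cyclically over trials)."""
    recs = []
    for subject in range(cfg.n_subjects):
        for trial in range(cfg.trials_per_subject):
            label = cfg.classes[trial % len(cfg.classes)]
            recs.append(generate_recording(cfg, subject, trial, label))
    return recs
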