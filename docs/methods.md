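# Methods

This note documents the models and procedures the package implements, the
defaults it ships, and what its synthetic benchmarks do and do not show.

## Problem setting

Subject-independent EEG emotion classification: given multichannel EEG
trials with binary emotion labels (high/low valence; scores binarized at a
3.0 threshold, boundary scores excluded), predict the label of segments from
a subject never seen in training. Evaluation is leave-one-subject-out (LOSO)
or leave-n-subject-out cross-validation; metrics are segment-level accuracy
and macro-F1, reported as mean ± SD over folds.

## Pipeline

### Temporal multi-scale features

Each trial (c × L, microvolts, sampling rate f_s) passes a two-level
segmentation: first-level sliding windows of l = 20 s with hop s = 4 s, then
per window K finer scales (l'_k, s'_k). Defaults: K = 3 with
(4 s, 2 s), (8 s, 4 s), (12 s, 6 s); the desk-scale configuration uses the
first two. Scale counts and lengths are package choices (any published
counterpart leaves them open) and are fully configurable.

Every sub-segment is summarized per channel by relative power spectral
density (rPSD) in seven bands: delta 1–4, theta 4–8, alpha 8–12, low-beta
12–16, beta 16–20, high-beta 20–28, gamma 30–45 Hz. Spectra use Welch's
method (Hann window, per-window length min(2 s·f_s, T), 50 % overlap, mean
averaging). Band power integrates the PSD over [f_lo, f_hi); the rPSD
denominator is the power over the union of the seven band supports (1–45 Hz
minus the 28–30 Hz gap), so each per-channel band vector sums to exactly 1 —
a strong invariant the tests pin. A full-spectrum denominator and absolute
PSD / differential-entropy features exist behind `feature_type` for
ablations. Zero-variance channels yield a zero row with a warning, never
NaN. Per scale k the features form tensors F_k of shape (b, n_k, c, 7).

### Spatial graph priors

Per scale, node features come from a learnable transform of the
batch-averaged tensor: Z' = Z W + V with Z the (c × 7·n_k) flattening
(sequence-major, band-minor — the order is a documented convention), W
Xavier-uniform, V zero. The global adjacency gates channel pairs jointly on
Pearson correlation (≥ its 75th percentile) and Manhattan distance (≤ its
25th percentile), computed over off-diagonal upper-triangle pairs only
(including the self-pairs would distort both thresholds); survivors get
Gaussian-kernel weights exp(−‖u_i−u_j‖² / 2σ²) with σ = (μ_d + σ_d)/2 from
the off-diagonal Euclidean distances. Diagonals are fixed to 1 (the kernel
at zero distance with both gates trivially passing). The local adjacency
masks the global one to same-region pairs. Both graphs are duplicated into
(2, c, c) stacks whose slices feed the shallow and deep encoders; the
slices start identical and are not trained apart.

Graphs are rebuilt per training batch from the current batch statistics and
transform parameters; gradients flow through the kernel weights into W and
V, while the percentile thresholds, σ, and the Laplacian λ_max are treated
as constants of the backward pass (order statistics and eigensolves are not
usefully differentiable at this scale). At evaluation the graphs frozen
from the best training epoch are reused, so no evaluation-batch statistics
leak across samples.

Region maps ship as editable JSON for a 62-channel montage (7-, 10- and
17-region lobe groupings) and a 32-channel montage (7 regions). The
groupings follow standard 10–20 lobe anatomy; they are configuration, not
hard-coded.

### Graph encoders and token fusion

Four Chebyshev spectral convolutions per scale — shallow (1 layer) and deep
(2 layers) for each of the global/local graphs — plus a linear base
embedding of the flattened features. A convolution layer computes
ReLU(Σ_{i<I} T_i(L̂) F θ_i − B) with T_i the Chebyshev polynomials of
L̂ = 2 L_sym/λ_max − I; λ_max is computed exactly (c ≤ 64 makes the
eigensolve cheap). The Chebyshev order defaults to I = 3. The bias enters
subtractively as written; the sign is absorbed by the trainable parameter.
Encoder outputs (b, n_k, c, w_out) are flattened over channels and affinely
projected to the hidden width h = 32 (one head per stream); some
channel-collapse map is forced by the required (b·n_k, h) token shape, and
a shared affine projection is the minimal choice. Per stream the base
embedding and the two encoder outputs are fused by an unweighted
elementwise mean. Encoder and projection weights are shared across scales
(their shapes do not depend on n_k); only the graph transforms are
per-scale.

### Temporal model

Token sequences (b, n_k, h) pass a residual pre-norm stack of M = 1
selective state-space blocks: x_m = Block(RMSNorm(x_{m−1})) + x_{m−1},
closed by a final RMSNorm (ε = 1e−6). Each block expands to
d_inner = 2h, applies a causal depthwise convolution (kernel 4, left
padding kernel−1) with SiLU, then the selective scan

    x_t = exp(Δ_t·A)·x_{t−1} + Δ_t·B_t·v_t,   y_t = C_t·x_t + D·v_t

with diagonal negative A (S4D-real initialization A[:, k] = −(k+1), stored
in log space), input-dependent Δ_t (through a dt_rank = ⌈h/16⌉ bottleneck
and softplus, so Δ_t > 0 and the decay factors lie in (0, 1]), B_t, C_t of
size d_state = 16, and Euler discretization of the input term (Δ_t·B_t, as
the recurrence is written). A SiLU gating branch multiplies the scan output
before the closing projection. Dropout 0.25 applies to the block output
before the residual add (the conventional pre-residual spot). Global and
local streams of every scale share one stack (halves the parameters; a
config switch separates them). The scan executes exactly n_k recurrence
steps per pass — the linear-time contract is asserted by a step counter,
not wall clock.

### Pooling and classification

Per stream and scale: mean over tokens, L2-normalization (ε = 1e−12);
global and local are averaged, then scales are averaged, giving x_final
(b, h). A linear head y = x_final W + b produces logits; softmax appears
only in the loss and at inference.

### Training

Cross-entropy with label smoothing 0.1, AdamW (lr 3e−4, weight decay 0.01),
batch size 32, early stopping with patience 5 on validation accuracy, the
highest-validation checkpoint evaluated on the test subjects. Validation
ties resolve to the later epoch: on easy synthetic tasks validation
saturates immediately, and keeping the longer-trained model is the natural
reading of "highest validation accuracy". Training is deterministic given
the seed (single-threaded NumPy). Folds: LOSO (remaining subjects split 8:2
train/validation by subject) or leave-n-out (⌈S/n⌉ folds, 9:1 split); no
subject ever straddles a boundary, asserted at fold construction.

The network runs on a package-internal reverse-mode autodiff tape over
NumPy arrays (see `msgm.autodiff`): the model sizes here (c ≤ 64, h = 32,
n_k ≤ 9) make a dense-array tape fast on one CPU core, and the per-step
scan loop doubles as the reference the vectorizable parts are tested
against.

### Ablation switches

Exactly one of: `no_temporal_multiscale` (keep the longest window only),
`no_spatial_multiscale` (local graph = global graph), `single_gcn` (one
depth-1 encoder per stream), `no_fusion` (tokens are the base embedding
alone), `no_mamba` (temporal stack replaced by identity; the scan counter
reads zero).

### Comparison statistics

Welch's t-test between per-fold accuracy lists or (mean, SD, n) summaries:
t = Δ/√(s_a²/n_a + s_b²/n_b), Welch–Satterthwaite degrees of freedom,
two-sided p, Cohen's d = Δ/√((s_a²+s_b²)/2). Published benchmark summaries
ship as a CSV (SEED n = 15 folds, THU-EP and FACED n = 10).

## Synthetic data generator

The generator emulates the statistics the pipeline assumes of emotion-EEG
corpora: per (region, band) one latent sinusoid (random frequency inside
the band with a 10 % edge margin, random phase) shared by the region's
channels; 1/f^α background noise (α = 1) mixed from region-shared and
private streams so channels correlate within regions (the mixing weight is
solved in closed form from the requested total correlation, clamped where
the shared oscillators already exceed it); a per-subject global gain
(lognormal, σ = 0.15) and per-band gain jitter (σ = 0.10) emulating
skull-thickness/impedance variability — the global gain cancels in rPSD
(the point of relative features), the band jitter does not, which is what
makes LOSO transfer non-trivial. Oscillator amplitudes are calibrated so
single-trial band SNR ≈ 1: learnable but not trivial. The "high" class
scales the alpha oscillator amplitude by (1 + effect_size), i.e. band power
by (1 + effect_size)². Everything is deterministic given
(seed, subject, trial).

What it does not emulate: video-evoked nonstationary dynamics, eye-blink or
EMG artifacts, volume-conduction mixing across regions, electrode drift, or
any ICA-style preprocessing. A note on relative features: because rPSD rows
sum to 1, boosting one band necessarily depresses the relative power of all
others slightly; class contrast is therefore *concentrated* in the effect
band rather than perfectly confined to it. Passing benchmarks on this
generator show the pipeline wiring, optimization and protocol are sound —
not that comparable accuracy would be reached on real recordings.

## Desk-scale benchmarks

The shipped conditions (`configs/small.yaml`, `msgm.experiments`): 8
subjects × 4 trials of 44 s, 16 channels in 4 regions, f_s = 128 Hz, scales
(4 s, 2 s) and (8 s, 4 s), alpha effect_size 1.0, 15 training epochs. These
sizes keep one full LOSO run in the low minutes on a single core while
leaving per-fold transfer non-trivial. Expected behavior, recomputed by
`scripts/acceptance.py` and the acceptance tests: LOSO accuracy well above
90 % with the alpha contrast, chance-level (40–60 %) with effect_size 0,
and no single-component ablation beating the full model by more than the
tolerance over three seeds.

## Numerical choices and edge cases

- PCC guard: 1e−6 added to the standard-deviation denominator; constant
  feature rows stay finite.
- σ ≤ 0 (all-identical node features) falls back to an indicator kernel.
- Isolated nodes get zero rows in the normalized Laplacian; the priors
  always carry a unit diagonal, so degrees stay positive inside the model.
- λ_max < 1e−12 (edgeless graph) short-circuits L̂ = −I.
- EDF export quantizes to int16 against the printed physical maximum so a
  read-back reproduces the writer's scaling bit-for-bit; it requires integer
  sampling rates and whole-second durations rather than padding silently.
- Non-finite losses abort a fold with a diagnostic rather than continuing.
- Valence exactly 3.0 is excluded with a warning rather than assigned to a
  class (avoids an arbitrary class bias).

## Known limitations

- The autodiff tape favors clarity over throughput; batch sizes and channel
  counts beyond a few hundred would want a compiled backend.
- Graph thresholds being batch statistics means very small batches produce
  noisy priors; batches of fewer than two samples are skipped in training.
- The 62/32-channel region JSONs approximate lobe groupings; they are
  montage conventions, not fitted anatomy.
- Multi-class (d_out > 2) runs are supported but the shipped benchmarks and
  generator defaults are binary.
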