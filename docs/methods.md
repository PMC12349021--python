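# Methods

## Problem setting

The package classifies emotional state from multichannel EEG organised the
way the DEAP corpus is: per subject, 40 trials of 63 s (3 s resting
baseline + 60 s audio-visual stimulus) recorded from 32 electrodes of the
international 10–20 montage at 128 Hz, each trial labelled with
self-reported valence and arousal on a 1–9 scale.  Ratings ≥ 5 count as
"high", < 5 as "low"; the two binarisations combine into the four
circumplex quadrants HVHA / HVLA / LVHA / LVLA.

## Feature chain

1. **Band decomposition.**  Each trial is filtered into theta (4–8 Hz),
   alpha (8–13 Hz), beta (13–30 Hz) and gamma (30–45 Hz) with an order-4
   Butterworth band-pass applied forward–backward (`sosfiltfilt`), i.e.
   zero phase and effective order 8.  The order is the EEG-community
   default; filtering runs over the whole 63 s trial so that 0.5 s slices
   carry no per-slice filter transients.
2. **Slicing.**  Non-overlapping 0.5 s windows (64 samples); a 60 s
   stimulus yields 120 slices, the 3 s baseline 6.
3. **Differential entropy (DE).**  Per band, channel and slice,
   `DE = 1/2 ln(2*pi*e*sigma^2)` with the unbiased (n−1) sample variance —
   the Gaussian closed form.  Constant segments are rejected rather than
   returned as −inf.
4. **Band power (PSD path).**  Channels are average-referenced first
   (common-mode removal), then each slice is Hanning-tapered
   (`w(n) = 0.5(1 − cos 2πn/(N−1))`), zero-padded to `N_FFT = 128` (bin
   width exactly 1 Hz) and transformed; the one-sided periodogram is
   `|X(f)|^2 / N_FFT` with a single segment (`K = 1`).  This deliberately
   follows the plain `1/(K·N_FFT)` normalisation rather than the
   window-energy-compensated convention of `scipy.signal.welch`; absolute
   powers differ from scipy's by a constant factor, relative structure
   does not.  Band power sums the PSD bins inside the band, both edges
   inclusive (a shared-edge bin such as 8 Hz contributes to both
   neighbouring bands), times the bin width.
5. **Baseline correction.**  The mean feature matrix of the six baseline
   slices is subtracted from every stimulus slice, separately for DE and
   band power.  The correction is feature-space (the common DEAP recipe)
   and a pure mean shift.

The DE path uses the raw (not re-referenced) band-filtered channels; the
average reference is applied on the PSD path only.  This asymmetry is a
defining property of the method and is load-bearing for the
complementary-signal experiments below.

## Tensorisation

Per slice and band, the 32 channel features are scattered onto an 8×9
scalp grid (rows front→back, columns left→right; 40 of the 72 cells carry
no electrode and stay exactly zero — no interpolation).  The four DE band
grids stack into a 4×8×9 tensor, likewise the four band-power grids, and
the two stacks concatenate DE-first into the fused 8×8×9 input tensor.
Eight consecutive fused tensors (4 s) form one model input sequence;
sequences are non-overlapping and never straddle trials.  The grid
placement is configuration-overridable (YAML mapping channel → cell)
because published 2-D montage drawings differ in minor cell choices.

## Network

Input `(B, 8, 8, 8, 9)`; batch and time fold together for the spatial
stage (`B·8` frames) and unfold before the recurrent stage:

| stage | output | notes |
|---|---|---|
| conv1–conv3 | 64/128/256 × 8×9 | 3×3, same-padding, bias, ReLU |
| Inception | 256 × 8×9 | 4 branches × 64 ch: 1×1; 1×1(32)→3×3; 1×1(16)→5×5; 3×3-pool→1×1 |
| max-pool 2×2/2 | 256 × 4×4 | flatten → 4096 |
| BiGRU ×2 | 8 × 256 | hidden 128/direction, single bias per gate |
| MHA | 8 × 256 | 4 heads × 64, bias-free Q/K/V/O projections |
| head | 1296 → 512 → n | mean over the 8 attended steps, ReLU between FCs, softmax |

Parameter counts of the constructed layers: conv1 4 672, conv2 73 856,
conv3 295 168, attention 4·256² = 262 144, output layer 2 052.  The
Inception branch widths (64 per branch with 32/16-wide reducers) are the
GoogLeNet-style choice; no published width set reproduces every printed
layer-table total under any standard bias convention, so totals for the
Inception block, BiGRU and the two hidden FC layers follow from the
construction here (Inception 89 392; BiGRU 3 540 480; fc1 333 072;
fc2 664 064).

The implementation is pure NumPy: im2col + GEMM convolutions, explicit
backpropagation through time for the GRUs, analytic softmax/attention
gradients, Adam.  Everything runs in float32 for training; float64 is a
config switch (`dtype`) used by the oracle-equivalence tests, which match
independent brute-force implementations of the GRU step and of per-head
attention to 1e−10.  Initialisation is He-normal for convolutions and
Glorot-uniform for linear/recurrent/attention weights, all biases zero,
seeded through the model config.

Ablation variants derive from the same config: `de_only` / `psd_only`
(4-channel input), `uni_gru` (forward-only, per-step width 128),
`no_gru` (conv features feed the attention directly, model width 4096),
`no_inception` (conv3 straight to pooling), `no_mha` (BiGRU output to the
head).  Downstream widths adapt automatically.

## Training and evaluation protocol

Within-subject five-fold cross-validation: each subject's sequences are
randomly partitioned into five near-equal folds (partitioning *sequences*,
not 0.5 s slices, so one model input never straddles train/test); each
fold serves once as the test set and a freshly initialised model trains on
the rest with Adam and cross-entropy.  Features are z-scored per tensor
channel with statistics from the training folds only; structurally zero
cells stay zero.  Fold accuracies pool across subjects into mean ± SD, and
fold-paired two-sided t-tests compare variants.  The full-data protocol is
batch 100, 100 epochs, learning rate 1e−3.

**Desk profile.**  The self-contained profile used by the tests runs two
synthetic subjects, 8 trials each (two per quadrant), 16 s stimulus + 3 s
baseline, gain strength 3, noise SD 1, ten epochs, batch 4.  At batch 4
the protocol learning rate is rescaled by the square-root batch rule
(1e−3·√(4/100) = 2e−4) and gradients are clipped at global norm 5; at the
protocol rate the tiny-batch Adam updates are large enough to throw the
optimiser into divergent loss spikes on a minority of folds.  These two
stabilisers apply only where a config sets them; the paper-scale profile
keeps the plain protocol.

## Synthetic data

The generator emulates the DEAP *format* and a controllable class signal,
not EEG physiology.  Each trial draws a quadrant (balanced, shuffled
order), then ratings uniformly from the matching halves of the 1–9 scale.
The signal per channel is one sinusoidal carrier per band (6/10/20/38 Hz,
random phase per trial/channel/band) plus white Gaussian noise; stimulus-
period carrier amplitudes are scaled by a per-class, per-band, per-region
gain map (default: frontal beta+gamma up for high arousal, posterior alpha
up for high valence), while the baseline keeps neutral gains.  Band-power
contrasts are therefore analytic (a carrier of amplitude `a` contributes
`a²/2` to its band's variance), which the tests exploit with independent
bandpass-and-variance oracles.

**Complementary-modality configuration.**  DE and band power are both
per-channel band-energy functionals of the same signal, so one cannot make
them complementary by band gains alone.  The configuration instead uses
the average-reference asymmetry of the feature chain:

* valence is encoded in the amplitude of a *spatially common-mode* alpha
  carrier (identical waveform on all 32 channels).  DE sees the raw
  channels, so its alpha variance moves with the class; the average
  reference removes a common-mode component exactly, so band power is
  blind to it.
* arousal is encoded in the *sign pattern* of a fixed-amplitude beta
  carrier: all channels in phase (high coherence) versus half the
  channels sign-flipped.  Per-channel variance — hence DE — is identical
  in both cases; after average referencing the in-phase pattern cancels
  while the alternating pattern survives, so band power sees the class.

A DE-only model can then separate valence but not arousal (quadrant
accuracy ≈ 50 %), a PSD-only model the reverse, and the fusion can solve
all four quadrants — the directional ablation the desk tests check.

What the generator does **not** model: 1/f background spectra, volume
conduction, artifacts, non-stationarity, inter-subject variability.
Passing desk-scale tests therefore demonstrates that the pipeline's
machinery (features → tensors → network → protocol) is correct and can
learn the class structure it is pointed at; it says nothing about
accuracy on real EEG, and the published full-scale DEAP accuracies are
out of scope of synthetic runs (the `paper-scale` preset documents the
protocol but requires the user-supplied DEAP download).

## Numerical and degenerate-input choices

* Constant segments (zero variance) raise rather than yield −inf DE;
  zero-variance hidden states likewise reject correlation estimation.
* Band edges at or above Nyquist are rejected at validation.
* `n_FFT` below the window length is an error; non-power-of-two lengths
  warn only.
* Fold partitions, generator draws, model initialisation and minibatch
  order all derive from explicit seeds; identical seed + config is
  bit-identical end to end on a given platform.
* The temporal aggregation before the head is the mean over the eight
  attended steps ("last step" is available by config); the layer table's
  published input to the first FC layer fixes only the width, not the
  reduction.
* The GRU temporal-correlation analysis correlates hidden vectors across
  units within a sample, then averages matrices over samples; which of
  the two stacked layers is inspected is configurable (default: last).

## Problem sizes used by the checks

The automated checks run the full-size architecture (≈ 4.6 M parameters)
throughout; only the data volume is scaled: the bookkeeping check pushes
one full 40-trial subject through the feature chain and counts the slices
of all 32 generated subjects, and the learning checks run the desk profile
above (2 × 32 sequences; complementary runs use one subject).  These sizes
are the package's desk-scale defaults and keep a complete run on a single
CPU core in the ten-minute range.
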