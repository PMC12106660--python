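# Methods

This note documents the models, the synthetic world, the numerical
choices, and what the tests do and do not establish.

## The decoding task

Each trial is a labeled multichannel epoch around sniff onset (−1…+4 s;
neural modalities 512 Hz, sniff 400 Hz). The label is binary: odor (1) vs
clean air (0); odor trials additionally carry an intensity condition
(high/low). The default analysis keeps the high-contrast subset (clean air
+ high-intensity odor, 20 + 60 trials per participant in the full design)
and asks a per-participant classifier to score single trials. Performance
is AUC-ROC computed as the exact Mann–Whitney rank statistic (ties count
1/2); this equals trapezoidal ROC integration but avoids threshold grids.

## Synthetic sessions

The generator states the world the tests live in; it is not fitted to any
recording, and its defaults are not claims about real data (per-trial SNR
of the real recordings is unknown).

- **Background**: per channel, Gaussian noise with a 1/f^β spectrum
  (β = 1 by default), unit variance, spatially mixed by a random
  channel-smoothed matrix (identity + 0.35·smoothed noise, row-normalized)
  as a minimal volume-conduction surrogate.
- **Odor effect**: on each odor trial, two band-limited bursts — beta
  (10–30 Hz) and gamma (50–95 Hz) — with Hann envelopes over the response
  window 0.5–1.0 s, center jittered by N(0, 0.05² s), carrier frequency
  uniform in band, random phase. Peak amplitude = `amplitude` ×
  intensity scale (1.0 high, 0.5 low) × a smooth positive per-channel gain
  profile. `amplitude` is a unitless SNR multiplier relative to the
  unit-variance background; the default 1.0 makes the effect clearly
  decodable (nested-CV AUC ≈ 0.9), `0` gives an exact null in which odor
  and air trials are exchangeable.
- **Sniff**: temperature proxy, 0 before onset, a negative half-Gaussian
  dip bottoming at 0.6 s (depth 1, onset width 0.35 s), recovery width
  0.9 s stretched by (1 + 0.4) on odor trials, plus 5 Hz-low-passed sensor
  noise (SD 0.05). The dip/recovery shapes are phenomenological, not
  physiological.
- **Reproducibility**: one RNG stream per modality, spawned from the
  session seed, so any modality regenerates identically in isolation.

Not emulated: ocular/muscle artifact morphology (rejection is exercised via
amplitude outliers), inter-channel forward-model structure, olfactometer
timing jitter, habituation. A green pipeline test therefore establishes
correctness of the *computation*, not performance on real recordings.

## Preprocessing

Zero-phase filtering throughout (forward–backward application), because
the analysis windows are time-locked: the 120 Hz low-pass is a
Hamming-window FIR with transition bandwidth 25% of the cutoff; the 50 Hz
power-line notch is a zero-phase IIR notch (Q = 30) — an FIR of comparable
notch width at 512 Hz would need thousands of taps. Resampling is
polyphase. Artifact rejection takes, per trial and channel, the maximum of
the Hilbert envelope, z-scores it across trials within channel, and drops
trials whose maximum z over channels exceeds 7. Note the z of a single
outlier among n trials is bounded by (n−1)/√n, so the 7-SD rule only has
teeth for sessions of ≳60 trials — consistent with its use on full
sessions. Baseline subtraction uses −1…−0.6 s; trial normalization divides
by the 95th percentile of |x| pooled over channels and samples. Windows
are half-open [t₀, t₁) in sample indexing.

## Features

Morlet TFR with 3 cycles (σ_t = n_cycles/2πf), wavelet support ±5σ_t,
amplitude-normalized so a unit sinusoid at the wavelet frequency yields
power ≈ 1. The transform runs on the full epoch and is cropped afterwards,
keeping the analysis window free of edge effects (a regression test pins
this down). The frequency grid is 1 Hz steps over 5–100 Hz by default;
protocol-level simulations use coarser steps (3–6 Hz) purely for CPU
budget — the binning contract (5 equal bins over 10–70 Hz, edges
10/22/34/46/58/70) is unchanged. Baseline correction is
log10(power/baseline mean) with an ε = 1e−12 guard instead of a hard error
on zero power. TFR time courses are decimated to ~50 samples/s before
flattening (power at 3 cycles is smooth at that scale); sniff features are
the 50 Hz-low-passed, 200 Hz-resampled temporal samples with PCA keeping
95% variance (component count unstated upstream; fitted on training folds
only).

## Decoders

**Linear**: L1 logistic regression; C tuned over {e^x : x = −1…9} (the
printed grid's bounds read as integers; 11 values). The contract-level op
uses the saga solver so the extreme-penalty limit is exact: when all
coefficients are zero the intercept is set analytically to logit(class
rate), the closed-form optimum of the intercept-only likelihood, because
iterative solvers stall in that flat regime. The pipeline factory uses
liblinear (orders of magnitude faster across the grid at ~10³ features)
inside a per-fold pipeline of (optional PCA →) standardization → fit, so
feature statistics never see validation or test trials.

**ResNet-1D**: stem convolution + 4 residual blocks (2 convolutions each,
kernel 17, filters 16→32→64→128, stride-2 once per block, batch
normalization + ReLU, 1×1 stride-2 skip projection) + global average
pooling + 1 sigmoid unit = 9 convolution layers. Implemented in numpy with
manual backpropagation (im2col convolutions); He initialization; AdamW
(decoupled weight decay 0.01, betas 0.9/0.999), mean BCE loss, batch 16,
reduce-on-plateau (÷10 after 15 stale validation epochs), checkpoint at
minimum validation loss, 70 epochs for neural modalities and 50 for sniff.
Filter counts/kernel sizes are configurable defaults of this architecture
family, not claims. Augmentation: Gaussian noise (0.1 of per-trial SD),
contiguous temporal mask (10% of samples), temporal shift (≤50 ms), each
applied per trial with probability 0.5. Batch order and augmentation draw
from separate RNG streams so augmentation on/off comparisons are paired.
Desk-scale runs (tests, analysis drivers) narrow the net to base 8 filters
and 15–20 epochs at learning rate 1e−3; the reference recipe remains the
default `TrainSpec`.

**Fusion**: "weighted by validation performance" is implemented as
w ∝ max(val AUC − 0.5, ε), renormalized — chance-level members get ~zero
weight, and if all members are at chance the ensemble degrades to a plain
average. Early fusion requires rate-harmonized inputs (sniff upsampled
200→256 Hz by polyphase resampling). The hybrid model trains both encoders
and the fused linear head jointly end-to-end (whether the original
encoders were frozen is unstated; joint training is the natural reading).

## Evaluation protocol

Stratified 10-outer/10-inner nested CV. Per outer fold: hyperparameters
(C, or the analysis window) are selected by mean inner-validation AUC
(ties → smaller C / earlier window); k_inner models are trained on the
inner training splits and ensembled with validation-AUC weights; the
ensemble is scored once on the untouched outer test fold. A fold-plan
audit asserts that no test trial ever appears in any fitting, scaling,
PCA, or selection step. `plain_kfold_with_selection` implements the leaky
alternative (selection and reporting on the same folds) solely to
demonstrate its optimism on null data. For the network, the inner
validation fold doubles as the checkpoint/scheduler monitor, which is what
the recipe prescribes.

## Group statistics

Per participant: trial-averaged spectrogram contrast (odor − air), channel
averaged, log-ratio units, 4–100 Hz × −0.2…1 s. Across participants:
per-bin dependent-samples t (df = N−1; zero-variance bins → t = 0 with a
warning). Cluster test: two-sided parametric threshold at cluster-forming
α = 0.05, clusters by 4-neighbor adjacency separately per sign, mass = Σt,
null from 100 random whole-participant sign flips using the maximum
absolute cluster mass, p = (1 + #{null ≥ |mass|})/(permutations + 1) —
so p ≥ 1/101, and Monte-Carlo SE shrinks with more permutations. The
cluster-forming threshold and the mass statistic follow the reference
toolbox conventions for this test; both one-sided variants are recoverable
by sign.

## Scaling choices for CPU budgets

Simulation-heavy checks run scaled down and say so: desk-scale sessions
(2 blocks × 30 trials, 16 EEG channels), 4–6 Hz TFR grid steps for
protocol simulations, 12-participant cohorts for cluster calibration, and
the narrow network above. The augmentation-parity check pools 5-fold
cross-validated predictions over 12 seeds (60 trainings per condition):
single trainings of a small net on ~24 trials vary by far more than any
augmentation effect, so only an averaged estimate makes a 3-point
equivalence band meaningful.

## Known limitations

- The generator's effect is stylized (stationary bursts, fixed bands); it
  cannot probe feature robustness to non-stationary or cross-frequency
  structure.
- Source reconstruction is out of scope: synthetic source-EBG epochs stand
  in for reconstructed ROI activity.
- ICA-based ocular artifact removal is out of scope (the synthetic data
  contains no ocular components); rejection handles amplitude outliers
  only.
- The numpy network is desk-scale by construction; it is not a
  performance-parity reimplementation of a GPU training stack.
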