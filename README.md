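# odorbci

Single-trial decoding of odor registration from multimodal olfactory
bio-signals.

## The problem

Can a machine-learning model tell, from one trial's worth of non-invasive
recordings, whether a person just smelled an odor or clean air? This is the
core question for olfactory brain–computer interfaces. The signals of
interest are 64-channel scalp EEG, the 4-electrode electrobulbogram (EBG —
forehead electrodes optimized for the human olfactory bulb), source-
reconstructed olfactory-bulb/piriform activity ("source-EBG"), and the
intranasal thermistor sniff trace. Odor processing expresses itself as
beta (10–30 Hz) and gamma (> 30 Hz) oscillatory power riding on the 1/f
EEG background, and as odor-modulated inhalation temperature dynamics.

This package implements the complete analysis as a reusable, tested
pipeline:

- **`synth`** — a synthetic session generator emulating the sniff-triggered
  design (4 blocks × 35 trials = 140 trials: 60 high- and 60 low-intensity
  odor, 20 clean air; epochs −1…+4 s around sniff onset) with injected
  band-limited beta/gamma bursts and an odor-stretched sniff dip. The real
  recordings are not public, so every stage is exercised on this stated
  surrogate world.
- **`preprocess`** — 50 Hz notch, zero-phase 120 Hz FIR low-pass, 256 Hz
  resampling, common-average reference, Hilbert-envelope artifact rejection
  (|z| > 7), −1…−0.6 s baseline subtraction, 95th-percentile trial
  normalization, sliding 250 ms windows with 100 ms overlap.
- **`features`** — 3-cycle Morlet time–frequency power (5–100 Hz), log10
  baseline ratio, 5 equal frequency bins over 10–70 Hz, fold-safe
  standardization and PCA (sniff).
- **`linear` / `net`** — the two decoders: L1 logistic regression with C
  tuned over {e⁻¹,…,e⁹}, and a 1-D residual CNN (stem conv + 4 residual
  blocks of 2 convs = 9 conv layers, sigmoid head) trained with AdamW
  (lr 5·10⁻⁵, BCE loss), reduce-on-plateau scheduling (÷10 after 15 stale
  epochs), min-validation-loss checkpointing, and noise/mask/shift
  augmentation. The network is implemented in pure numpy (manual backprop)
  — no GPU framework required.
- **`fusion`** — validation-AUC-weighted late fusion of probabilities,
  early channel-concatenation fusion, and a dual-encoder hybrid network.
- **`evaluate`** — AUC-ROC as the exact Mann–Whitney rank statistic,
  stratified 10×10 nested cross-validation with validation-weighted inner
  ensembles, best-window selection, one-sample/paired t tests, and the
  deliberately leaky plain-K-fold protocol that demonstrates the optimism
  bias nested CV removes.
- **`groupstats`** — group spectrogram contrasts and the nonparametric
  cluster-based permutation test (dependent-samples t, ±t threshold,
  4-connectivity clusters, mass statistic, participant sign-flip null,
  100 Monte-Carlo permutations) plus the best/worst-performer split.
- **`store` / `pipeline` / `cli`** — HDF5 epoch container, BIDS-like
  events TSV, end-to-end orchestration, and a thin `odorbci` CLI
  (`generate`, `preprocess`, `decode`, `evaluate`, `groupstats`, `run`).

Key quantity: AUC-ROC = P(score of a random odor trial > score of a random
clean-air trial); 0.5 is chance. With n₊ positives whose rank sum is R₊:
AUC = (R₊ − n₊(n₊+1)/2) / (n₊ n₋).

## Worked example

```bash
python analysis/01_simulate_sessions.py --seed 0 --participants 2 --small
python analysis/02_decode_linear.py --k-outer 5 --k-inner 5
python analysis/06_cv_bias.py --n-seeds 4
```

prints (seed 0):

```
sub-00: 60 trials (40 odor / 20 air), 16 EEG ch @ 512 Hz
sub-00 scalp_ebg: mean test AUC 0.950
sub-00 sniff: mean test AUC 0.650
sub-01 scalp_ebg: mean test AUC 0.912
sub-01 sniff: mean test AUC 0.662
scalp_ebg: mean AUC 0.931, t(1) = 23.00, one-sided p = 0.014
...
null data: nested mean 0.369, plain-selected mean 0.519
plain > nested in 4/4 seeds (sign test p = 0.0625)
```

The first block decodes each synthetic participant with nested-CV L1
logistic regression: at the generator's default effect size the band-power
signature is easy (AUC ≈ 0.93 on scalp-EBG), while the sniff trace carries
weaker information (≈ 0.65). The second block shows the evaluation point
of the protocol: on *null* sessions the leaky plain-K-fold estimate sits
above the honest nested-CV estimate in every seed — the optimism bias that
nested cross-validation exists to remove. `analysis/03–05` run the
ResNet-1D decoder, the three fusion schemes, and the group-level cluster
permutation analysis the same way.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a 6-participant synthetic
cohort — generation, conditioning, time–frequency features, nested-CV
decoding, and the 100-permutation group cluster test — writes the run's
tables under `results/pipeline/`, and emits the acceptance JSON to the
path given by `--out`. All randomness derives from `--seed`.
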