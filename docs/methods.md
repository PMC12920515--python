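# Methods

This note documents the models, conventions, numerical choices, and
deliberate design decisions behind `envtrf`, and what the synthetic
validation studies do and do not establish about real data.

## Forward model and scope

All analyses assume the linear convolutional encoding model

    r(t, ch) = Σ_τ w(τ, ch) · s(t − τ) + b(ch) + ε(t, ch)

over lags τ ∈ [−100, 600] ms, where `s` is the broadband speech
envelope and `r` the (preprocessed) EEG. The package estimates `w` per
subject and condition, compares conditions at the sensor level, and
validates components against a stimulus-shuffled null. Backward
(decoding) models, multivariate spectrogram TRFs, and source-space
analysis are out of scope.

## Vocoder

`vocode` degrades speech the way cochlear-implant acoustic simulations
do. Analysis bank: N contiguous bands with geometrically spaced edges
`f_low·(f_high/f_low)^(i/N)` (default 4 bands, 200–5,000 Hz). Per band:

1. zero-phase Butterworth band-pass (scipy order 4, applied
   forward–backward);
2. half-wave rectification and zero-phase low-pass at 200 Hz (order-4
   Butterworth) → band envelope, clipped at 0;
3. a Gaussian noise carrier, **band-limited by the same filter before
   modulation**, multiplied by the envelope;
4. the modulated product band-passed again to confine modulation
   sidebands, and rescaled to the analysis band's RMS;
5. bands summed.

Band-limiting the carrier both before and after modulation doubles the
transition-skirt attenuation between adjacent bands. This matters
because contiguous Butterworth bands overlap in their skirts: with a
single confinement pass, a tone at a band edge leaks ~13–17 dB into the
neighboring measurement band purely through skirt overlap, which would
mask the vocoder's actual (much deeper) band separation. With the
double pass the non-adjacent-band attenuation for a 1 kHz tone is
~25–29 dB. Note that 1 kHz falls exactly on the shared edge of bands 2
and 3 of the default bank, so its energy necessarily splits between
those two bands; "out-of-band" means bands 1 and 4.

Envelope preservation is quantified as the Pearson correlation between
per-band envelopes of input and output. For this comparison the
envelopes are smoothed at 10 Hz (syllabic modulation rates) rather than
the vocoder's own 200 Hz cutoff: at 200 Hz the intrinsic Rayleigh
fluctuation of the independent noise carrier bounds the attainable
correlation near 0.7–0.95 in narrow bands regardless of how faithfully
the slow temporal envelope is preserved, so a 200 Hz comparison
measures carrier statistics, not envelope fidelity. With 5 s
amplitude-modulated noise inputs the per-band correlations are
0.94–1.00.

Silent input maps to silent output; identical carrier seeds give
bit-identical output.

## Auditory front-end

The TRF stimulus is the broadband temporal envelope: 128 sub-band
envelopes on log-spaced bands spanning 90–4,000 Hz (order-4 zero-phase
Butterworth band-passes, half-wave rectification, 30 Hz smoothing),
averaged uniformly across bands, polyphase-resampled to 256 Hz
(Kaiser-windowed), and clipped at 0. This is a **linear** approximation
of cochlear-model front-ends, which include compressive nonlinearities:
only the band-averaged temporal modulation survives downstream, and
that is dominated by the modulation itself rather than by cochlear
compression. Consequences: the envelope is exactly scale-equivariant
(scaling the audio by k scales the envelope by k), and absolute
envelope values carry no meaning — all fits z-score the envelope
per sentence anyway.

## EEG preprocessing conventions

- Band-pass 1–57 Hz: Hamming windowed-sinc FIR, odd length chosen for a
  ≤1 Hz transition at the low edge, applied with compensated delay
  (zero-phase) over reflection padding. The length is capped at
  2·n−3 taps when the signal is short.
- Resampling: polyphase (`resample_poly`), e.g. 2,048 → 256 Hz.
- Epochs: 3 s windows, −0.5…2.5 s around onset; the onset sample
  belongs to the epoch and windows are half-open [t_min, t_max).
- Repetition averaging: per-sentence mean of repeated presentations,
  then a 1–15 Hz zero-phase FIR on the averages.
- Baseline normalization: ONE scalar mean and sd computed from all
  pre-onset samples pooled across sentences AND channels, applied to
  every sample. Pooling (rather than per-channel scaling) preserves
  relative channel power, which the topographic analyses rely on. A
  zero pooled sd raises a degenerate-input error. The operation is
  idempotent to numerical precision.
- Alpha control: Welch PSD (1 s Hann segments, 50% overlap) per epoch
  at Pz and POz, averaged within 8–12 Hz, over epochs, and over the two
  sites; conditions compared by a two-tailed paired t-test across
  subjects.
- No artifact rejection, re-referencing, or channel interpolation.

## TRF estimation

- Lag grid: indices floor(t_min·fs/1000) … ceil(t_max·fs/1000)
  inclusive; (−100, 600) ms at 256 Hz gives lags −26…154, 181 lags.
  Envelope samples outside the epoch are zero-padded so all folds have
  equal length.
- Ridge: `Ŵ = (XᵀX + λ·m·P)⁻¹ XᵀY` with `m` the mean diagonal of the
  penalized block of XᵀX and `P` the identity with a zero for the
  intercept column. Scaling λ by `m` makes the grid invariant to
  stimulus scale. A rank-deficient system at λ = 0 raises an error
  advising λ > 0.
- Normalization: per sentence, the envelope is z-scored and the
  response is z-scored with a single pooled scalar (mean/sd over
  channels × time), preserving topography. Normalization can be
  disabled (`normalize=False`) for exact forward–inverse checks, where
  per-sentence scale factors would otherwise make a single common
  kernel unrepresentable and a noiseless baseline has zero sd.
- λ selection: leave-one-sentence-out. For each λ, fit on the remaining
  sentences, predict the held-out EEG from its envelope, average MSE
  over channels, time, and folds; average the curves over subjects; one
  joint argmin across the two conditions (grid: 13 powers of ten,
  10⁻⁶…10⁶).
- **Prediction vs estimation.** The CV-optimal λ minimizes prediction
  error, which is nearly blind to weight variance along the low-
  eigenvalue directions of the smooth (2–8 Hz) envelope design. On
  strongly averaged synthetic data the CV pick is tiny (~10⁻⁴) and the
  *shape* of the recovered kernel is noisy even though prediction is
  optimal. Kernel-recovery checks therefore evaluate at a moderate
  fixed ridge (λ = 1 in m-scaled units); condition contrasts on GFP are
  robust to either choice.
- Implementation: per-sentence normal-equation blocks are accumulated
  once; `batch_fit` factorizes the regularized system a single time
  (Cholesky) and solves for all subjects × conditions, in ~240 MB
  chunks. Responses may be stored float32 (a 50-subject study is ~2 GB
  in float64); the accumulation precision is selectable and float64 by
  default.

Prediction metrics (`score`): per-channel MSE and Pearson r, then
channel means; a constant prediction or response leaves r undefined
(NaN, excluded from the mean), never coerced to 0.

## Component statistics

- GFP: Lehmann–Skrandies spatial standard deviation across electrodes
  at each lag (population convention, divide by n_channels).
- Pointwise tests: two-tailed paired t (t = mean(d)/(sd(d)/√n),
  df = n−1). Degenerate differences: all-zero → (t=0, p=1); constant
  nonzero → (±inf, p=0), flagged rather than hidden.
- FDR: Benjamini–Hochberg step-up (via statsmodels), monotone adjusted
  q-values; significance is the strict rule q < α. One FDR family per
  analysis surface: all lags for time courses, all channels for
  topographies, windows × conditions for permutation summaries.
- Clusters: maximal runs of consecutive significant lags; endpoints are
  the first/last significant lag-sample times, not interpolated; a
  single-lag run is widened by half the sample spacing on each side.
  Clusters are labeled N1/P2/P400 when they overlap the canonical
  ranges 60–130, 130–250, 300–500 ms.
- Window amplitudes: channel-averaged TRF within a window, summarized
  by the mean or by the signed extremum (minimum for N1 windows,
  maximum otherwise). The sensor ROI for amplitude summaries is
  {FCz, Cz, CPz}.

## Permutation validation

The null pairing is a uniformly sampled derangement (rejection sampling
from uniform permutations), so no envelope keeps its own EEG — fixed
points would dilute the null. Valid and shuffled TRFs run through the
same fitting code; the pairing is the only difference (the identity
pairing reproduces the valid result bit-for-bit, asserted in tests).
One shuffle per subject by default, with optional averaging over
multiple shuffles. The shuffled fit reuses the λ of the valid fit.
Window amplitude for the comparison is the peak GFP within each window
(nonnegative, reference-free); comparisons are paired t with FDR over
windows × conditions. Cross-validated prediction metrics of both arms
are available (`compute_metrics=True`).

A caution established during validation: on *coupled* data the
shuffled-model Pearson r is slightly positive (~0.15 at the synthetic
noise level), not zero, because all sentence envelopes share onset
ramps and modulation statistics; only under a fully decoupled null is
the shuffled r centered at 0. Shuffled performance is a conservative
null, exactly as intended.

## Synthetic data generator

What it emulates: a passive-listening study with 2 conditions × 10
sentences × 100 repetitions per subject, 64-channel EEG (standard
Biosemi cap geometry) at 256 Hz, 3 s epochs (−0.5…2.5 s), ~50 subjects.

- Kernels: three Gaussian lag components — N1 (90 ms latency, 15 ms sd,
  negative), P2 (160 ms, 25 ms), P400 (390 ms, 30 ms) — with a shared
  fronto-central scalp gain (Gaussian in 3-D around the FCz/Cz
  midpoint, sd 0.045 m). Condition amplitudes: natural N1/P2 = 1.5,
  P400 = 1.0; vocoded N1/P2 = 1.0, P400 = 1.5 — the 1.5× early/late
  dissociation between clean and degraded speech, with 0.5 normalized
  units of P400 contrast.
- Subject variability: multiplicative amplitude factor (sd 20%) and
  latency shift (sd 10 ms) per component, drawn once per subject and
  shared across conditions (subject traits), keeping contrasts paired.
- Stimuli: nonnegative envelopes from half-wave-rectified 2–6 Hz
  narrow-band noise, smoothed below 10 Hz, 50 ms on/off ramps, unit sd,
  2.5 s — a speech-like ~4 Hz syllabic modulation spectrum.
- Noise: 1/f (exponent 1) Gaussian noise, exactly unit variance by
  construction, spatially correlated through a random mixing matrix
  smoothed over scalp distance (unit-norm rows). SNR is defined over
  post-onset samples: noise sd = √(P_signal/10^(SNR/10)), one sd per
  subject computed from the condition-averaged signal power so that
  condition contrasts are not renormalized away. Zero-amplitude (null)
  kernels leave SNR undefined; unit noise is used.
- Fast path: `simulate_averaged_study` draws the repetition-averaged
  responses directly with noise sd/√n_reps — exact in distribution for
  Gaussian noise under the linear averaging pipeline. The epoch-level
  `simulate_dataset` (used by the orchestrated pipeline and small
  tests) produces identical signals; only the noise realization paths
  differ.

What it does **not** emulate: real cochlear nonlinearities, artifacts
(blinks, muscle), non-Gaussian or nonstationary background EEG, volume
conduction from realistic sources, oscillatory (e.g. alpha) dynamics,
or repetition effects (adaptation). Passing the synthetic studies
establishes that the *pipeline* is correct and calibrated under its own
model assumptions — not that real EEG satisfies those assumptions.

Two generator-vs-reality findings worth knowing:

1. *Evoked alpha leakage.* The component kernels (sd 15–30 ms) carry
   genuine 8–12 Hz energy. At the synthetic single-epoch SNR of 0 dB,
   condition-dependent kernel amplitudes therefore inject a small but
   systematic condition difference in parietal alpha power — unlike
   real EEG, where single-epoch evoked energy is negligible against
   ongoing alpha. The alpha-control null study consequently uses the
   shared (across-condition mean) kernel, which realizes "no
   condition-dependent alpha injected" exactly; with it the paired test
   is calibrated (rejection ≈ 5% at α = 0.05 over 600 diagnostic runs).
2. *GFP noise floor.* Per-sentence pooled response scaling gives the
   two conditions slightly different weight-noise floors, visible as a
   pre-onset GFP difference at high effective SNR. Component inference
   restricted to post-onset windows is unaffected in direction.

## Validation studies: designs and problem sizes

Seeded studies in `envtrf.studies` (all randomness descends from one
seed; sizes chosen to keep the full battery under ~10 minutes on one
CPU):

| study | design |
| --- | --- |
| ridge oracle | 50 random 20×181 systems vs QR-based augmented least squares |
| noiseless recovery | 1 subject, 4 sentences, no noise, λ = 0, normalization off |
| kernel recovery | 50 subjects × 10 × 100 at SNR 0 dB, λ = 1, corr over 0–500 ms on peak-topography channels |
| λ monotonicity | 20 paired runs, 3 subjects, single repetitions, SNR ∓10 dB |
| null calibration | 200 datasets × 50 subjects, shared kernel, 16 channels, 64 Hz lag grid |
| headline contrast | 20 runs × 50 subjects, default kernels, full 64 ch/256 Hz; λ selected once on run 0 |
| permutation validity | one 50-subject coupled study at SNR 0 dB, planted windows (latency ± 2 sd) |
| permutation null | 200 datasets × 20 subjects, zero kernels, 16 ch, 64 Hz |
| vocoder physics | 2 s tone + three 5 s AM-noise inputs |
| FDR enumeration | exhaustive p-vectors up to length 6 over a 4-value grid |
| alpha null | 200 studies × 20 subjects, shared kernel, parietal sites only |

The reduced-dimension studies shrink only axes that the checked
property does not depend on (channel count, lag-grid rate); subject
counts, dataset counts, and repetition structure follow the full
design.

## Numerical choices

- Zero-phase IIR filtering uses second-order sections (`sosfiltfilt`)
  throughout; FIR filtering uses odd-length kernels with reflection
  padding and compensated delay.
- Pink noise is normalized by its exact ensemble variance (computed
  from the spectral gains), not per-realization, so SNR calibration is
  unbiased.
- Averaged-study responses are stored float32 (~2 GB per 50-subject
  study in float64 otherwise); solves are float64.
- CSV outputs use 9 significant digits; HDF5 containers hold epochs,
  envelopes, and TRF models; every pipeline artifact records the config
  hash and seed.
- Ties/degenerate cases: empty significance masks yield empty cluster
  lists; single-lag clusters are widened to the sample spacing;
  constant predictions yield NaN correlations; zero pooled baseline sd
  and single-channel GFP raise errors.

## Known limitations

- The linear front-end cannot replicate cochlear-model envelopes
  exactly; only the band-averaged modulation is comparable.
- The λ grid is 13 powers of ten; values between grid points (such as
  the intermediate optima a finer grid would find on real data) require
  a user-supplied grid.
- The cross-validated λ is a prediction optimum, not a kernel-shape
  optimum (see above); users interpreting TRF morphology should regard
  λ as a smoothing choice and report it.
- Sentence-level shuffling is the only implemented null; circular
  shifts and phase randomization are not provided.
- EDF/BDF reading is a thin wrapper (event extraction is left to the
  caller); the HDF5 container is the primary interchange format.
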