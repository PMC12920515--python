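# envtrf

Sensor-level analysis of EEG "neural speech tracking" under degraded
listening conditions: noise vocoding of speech, broadband envelope
extraction, temporal-response-function (TRF) estimation by ridge
regression, component detection on global field power, and
stimulus-shuffling permutation validation — exercised end-to-end on
synthetic EEG with known ground truth.

The package is aimed at auditory neuroscientists who compare cortical
envelope tracking between clean ("natural") and degraded
(noise-vocoded, cochlear-implant-like) speech. The scientific question
it operationalizes: clean speech drives larger *early* TRF components
(N1 around 90 ms, P2 around 160 ms), while degraded speech drives an
enhanced *late* positive component (P400 around 390 ms) — a signature
of delayed, compensatory processing. Because EEG recordings of this
kind are rarely shareable, the package ships a first-class synthetic
data generator that implements exactly the forward model the analysis
assumes, so every stage can be validated against planted ground truth.

## The model

The TRF is the linear kernel `w(τ, ch)` mapping the speech envelope
`s(t)` to the EEG response:

    r(t, ch) = Σ_τ w(τ, ch) · s(t − τ) + b(ch) + ε(t, ch),   τ ∈ [−100, 600] ms

Weights are estimated from the normal equations with a scaled ridge
penalty and an unpenalized intercept,

    Ŵ = (XᵀX + λ·m·I)⁻¹ XᵀY,   m = mean diag(XᵀX),

where `X` is the lagged-envelope design matrix. λ is selected by
leave-one-out cross-validation across sentences (grid 10⁻⁶…10⁶, MSE
averaged over channels and folds, one joint argmin across the two
conditions). Conditions are compared lag-by-lag on the global field
power GFP(τ) = sd over channels of `w(τ, ·)` with two-tailed paired
t-tests and Benjamini–Hochberg FDR; maximal runs of significant lags
form the component windows. Validity is established against a
stimulus-shuffled null: envelopes are deranged relative to the EEG (no
sentence keeps its own response) and the identical pipeline re-run.

Pipeline stages map to modules: `vocoder` (N-band noise vocoding,
log-spaced 200–5,000 Hz), `frontend` (128-band auditory spectrogram,
~90–4,000 Hz, averaged to the broadband envelope at 256 Hz),
`preprocess` (FIR filtering, resampling, epoching, repetition
averaging, pooled baseline z-scoring, parietal alpha-power control),
`trf`, `stats`, `permutation`, `simulate`, `studies` (seeded validation
studies), and `pipeline`/`cli` (orchestration).

## Worked example

Simulate a small two-condition study, fit every subject's TRF, and
detect condition-dominant component windows:

```python
from envtrf.simulate import SimConfig, simulate_averaged_study
from envtrf.trf import batch_fit
from envtrf.stats import compare_gfp, find_clusters, gfp, label_clusters

cfg = SimConfig(n_subjects=12, seed=0)          # 12 subjects, SNR 0 dB
study = simulate_averaged_study(cfg)
W = batch_fit(study.envelopes, study.responses, cfg.lag_spec, 1.0,
              onset_index=cfg.onset_index)      # [subj x cond x ch x lag]
g = gfp(W)                                      # spatial sd per lag
test = compare_gfp(g[:, 0], g[:, 1], cfg.lag_spec.times_ms)
for w in label_clusters(find_clusters(test.sig_mask, cfg.lag_spec.times_ms)):
    sel = (cfg.lag_spec.times_ms >= w.t_start) & (cfg.lag_spec.times_ms <= w.t_end)
    dom = "natural" if test.t_values[sel].mean() > 0 else "vocoded"
    print(f"{w.name}: {w.t_start:.0f}-{w.t_end:.0f} ms ({dom} dominant)")
```

prints

```
cluster_0: -102-16 ms (vocoded dominant)
N1_TRF: 39-227 ms (natural dominant)
P2_TRF: 246-273 ms (natural dominant)
P400_TRF: 289-301 ms (vocoded dominant)
P400_TRF: 316-527 ms (vocoded dominant)
cluster_5: 547-582 ms (vocoded dominant)
```

The planted contrast is recovered: natural speech dominates the early
windows, vocoded speech the late window. (After averaging 100
repetitions the effective noise level is low, so significant runs are
broad and merge across neighboring components; the pre-onset cluster
reflects the condition-dependent GFP noise floor introduced by
per-sentence response scaling — see docs/methods.md.)

The numbered drivers under `analysis/` run the full 50-subject
workflow (`01_simulate.py` … `05_alpha_control.py`), writing tables to
`results/`. A `envtrf` command-line tool exposes the file-level
operations (`envtrf vocode`, `envtrf envelope`, `envtrf simulate`,
`envtrf alpha`, `envtrf pipeline`).

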