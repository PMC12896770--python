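# ddkaug

Speech-based detection of Parkinson's disease (PD) from diadochokinetic
(DDK) recordings — rapid /pa-ta-ka/ syllable repetition — degrades in a
characteristic way under hypokinetic dysarthria: the syllable rate drops,
intensity modulation flattens, and timing becomes irregular. `ddkaug`
implements a complete, reproducible pipeline for studying how **spectrogram
data augmentation** and **training/model-selection strategy** affect a small
CNN classifier on this task, for researchers in pathological-speech
processing who want a tested reference implementation that runs anywhere
(pure NumPy/SciPy, no GPU).

Because clinical DDK corpora are access-restricted, the package ships a
first-class **synthetic cohort generator**: seeded, subject-structured
two-class pseudo-DDK audio whose class effects (rate deficit, modulation
deficit, noise excess) are tunable down to zero, so the full pipeline can
be validated — including chance-level calibration — without patient data.

## Pipeline

1. **Preprocess** — peak-normalize, downmix to mono, resample to 16 kHz,
   cut into 160 ms windows with 50% overlap (2560 samples, hop 1280).
2. **Mel frontend** — per window, an 80-band log-mel spectrogram
   (STFT window 256, hop 64, centered framing ⇒ exactly 80×41; dB relative
   to the window maximum, floored at −80 dB).
3. **Augment** (training partitions only; doubles the training set
   symmetrically per class):
   * waveform level: additive noise *x′(t) = x(t) + α n(t)* and circular
     time shift *x′(t) = x(t − τ)*;
   * spectrogram level: SpecAugment (SA), RandMasking (RM), RandMix (RMi),
     Cutting Masking (CM, block cut-and-paste from a same-class sample),
     Mixture Masking (MM, region blend λ·target + (1−λ)·source).
4. **Classify** — a 2D CNN: *n* blocks of (3×3 same-padded conv → ReLU →
   2×2 max-pool), channels 1→4→8→16→32, then fully connected 320→128→64→2.
   The 4-block default has 55,618 trainable parameters.
5. **Evaluate** — subject-level accuracy/sensitivity/specificity/F1
   (mean segment PD-probability per subject, threshold 0.5) under four
   strategies: train-100%, holdout 70/30, and subject-independent
   stratified 5-fold CV with *best-model* or *mean-model* selection.

## Worked example

```bash
cat > example.yaml <<'YAML'
seed: 7
train_cohort: {n_subjects_per_class: 10, duration_s: 2.0}
test_cohort:  {n_subjects_per_class: 5,  duration_s: 2.0}
training:     {max_epochs: 10, patience: 3}
methods:      [baseline, CM]
strategies:   [holdout, cv_mean]
YAML
ddkaug run --config example.yaml --out run1
```

prints (this exact output, since every cell is seeded):

```
strategy,method,accuracy,sensitivity,specificity,f1
holdout,baseline,1.00,1.00,1.00,1.00
holdout,CM,1.00,1.00,1.00,1.00
cv_mean,baseline,0.90 ± 0.22,0.80 ± 0.45,1.00 ± 0.00,0.80 ± 0.45
cv_mean,CM,1.00 ± 0.00,1.00 ± 0.00,1.00 ± 0.00,1.00 ± 0.00
```

Rows are subject-level metrics on the independent 5+5-subject test
cohort; CV rows additionally show mean ± SD of the per-fold validation
metrics. With the generator's default class effects the task is easy
(near-perfect separation); one baseline CV fold collapsed to the
positive class, which the mean-model row's spread makes visible —
exactly the kind of instability the strategy comparison is designed to
expose. `ddkaug generate` writes cohorts as 16-bit WAV plus a CSV
manifest if you want the raw audio.

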