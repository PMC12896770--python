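# Methods

## Synthetic DDK cohorts

The generator emulates the structure of a diadochokinesis task — a
subject repeating syllables at 4–7 Hz in one breath — not its phonetics.
Each syllable is a 10 ms white-noise burst (plosive release) followed by
a 60 ms exponentially decaying harmonic complex (8 harmonics, subject
f0 ≈ 120 Hz, 20 ms decay constant). Syllables are placed at the
subject's rate with Gaussian onset jitter (SD 8 ms for controls); a
continuous harmonic "bed" of amplitude (1 − modulation depth) flattens
the envelope, and white background noise (amplitude 0.005 re peak for
controls) is added before peak scaling to 0.9.

Class effects are deficits relative to the healthy-control means:

| parameter | HC default | PD default | unit / meaning |
|---|---|---|---|
| syllable rate | 5.5 | 5.5 − 1.0 | syllables/s; slowed DDK rate |
| modulation depth | 0.9 | 0.9 − 0.3 | envelope swing fraction; hypokinetic flattening |
| background noise | 0.005 | 0.005 + 0.02 | linear amplitude; breathiness proxy |
| onset jitter | 8 ms | 8·(1 + 2·depth-deficit) ms | timing irregularity |

HC means follow typical adult /pa-ta-ka/ rates; the deficit sizes were
chosen once to produce a clearly separable two-class problem at the
default settings, and every deficit scales continuously to zero, at
which point the two classes are drawn from identical distributions
(used for chance-level calibration). Between-subject variation is a
Gaussian random effect (relative SD 0.08) on rate, modulation depth and
f0, truncated to valid ranges.

Randomness is counter-addressed: subject traits come from the stream
keyed `(seed, class, subject)` and each recording from
`(seed, class, subject, recording)`, so enlarging a cohort never
changes existing subjects, and a fixed seed gives bit-identical audio.
What the generator does **not** model — formants, coarticulation,
channel/microphone variation, dysphonia beyond broadband noise — means
a classifier that is perfect here may still fail on real speech;
passing tests demonstrate pipeline correctness and calibration, not
clinical performance.

## Preprocessing

Order: peak normalization → mono downmix (channel mean) → polyphase
resampling to 16 kHz → segmentation into 2560-sample windows at hop
1280. Peak (rather than RMS) normalization keeps samples in [−1, 1]
for 16-bit I/O and makes the whole pipeline invariant to input
pre-scaling. Incomplete tail windows are dropped (no zero-padding) so
every downstream matrix is exactly 80×41; a recording shorter than one
window yields an empty list and a logged warning.

## Mel frontend

STFT: Hann window of 256 samples, hop 64, centered (reflect-padded)
framing — chosen because it yields 1 + ⌊2560/64⌋ = 41 frames per
window; uncentered framing would give 37 and break the input contract.
Power spectra are projected onto an 80-band Slaney-style mel filterbank
(0–8000 Hz, area-normalized triangles); with 129 FFT bins a few
low-frequency triangles can cover no bin center, and such bands simply
sit at the floor. dB conversion is 10·log₁₀(power/ref) with ref = the
segment's matrix maximum and a floor at −80 dB, making the
representation scale invariant and bounded in [−80, 0]. An all-zero
segment maps to a uniform floor matrix. Window shape, centering,
power-vs-magnitude and the dB reference are genuinely open choices and
are isolated in one module.

## Augmentation

Operator magnitudes are configuration, with defaults: noise intensity
α = 0.05 (re unit peak), shift fraction τ/N = 0.1, SA one time mask
≤ 8 frames and one frequency mask ≤ 12 bands (widths uniform including
zero), RM/RMi three blocks ≤ 16 bands × 10 frames, CM/MM one region
with height ~ U{1..80} and width ~ U{1..41} (expected area ≈ 26% of the
matrix), MM blend weight λ = 0.5. Masks fill with the −80 dB floor by
default (matrix mean exposed). Time shifting is circular, preserving
the sample multiset. Block sources are drawn uniformly from *same-class*
items of the current batch and labels are never mixed; an item whose
class has no other member passes through unaugmented and is logged.
`expand_training_set` returns originals plus exactly one augmented copy
per original (techniques composed in listed order), so the training set
doubles with class balance preserved. The waveform-combo preset applies
noise then shift before the spectrogram is computed.

## Network and training

The CNN is implemented directly in NumPy (im2col convolution, 2×2
floor-division max-pooling, explicit backward passes, verified against
finite differences). No batch normalization or dropout. Weight
initialization is uniform ±1/√fan-in, seed-controlled. ReLU follows
each of the first two fully connected layers. Training uses softmax
cross-entropy and Adam (lr 10⁻³, β = 0.9/0.999), batch 64, at most 100
epochs with early-stopping patience 10 — all exposed in `TrainConfig`.
Inputs are mapped from [−80, 0] dB to [−0.5, 0.5].

Model selection uses subject-level validation accuracy. `TrainConfig.
select_by_validation` can disable best-epoch restoration: that matters
when the validation fold itself is the quantity being estimated
(chance-level calibration), where selecting the best epoch on the same
fold would bias the estimate upward. The train-100% strategy has no
validation signal, so it runs a fixed epoch budget (`train100_epochs`,
default `max_epochs`).

RNG streams are named and independent: fold assignment, holdout split,
weight init and batch shuffling each derive from `(seed, stream-id)`,
and each CV fold trains from its own derived seed so a single
pathological initialization cannot sink all folds identically.

## Evaluation

PD is the positive class. Segment PD-probabilities are averaged per
subject and thresholded at 0.5 (tie ⇒ PD); metrics are computed on the
resulting subject-level confusion matrix, which is the only granularity
at which rates like specificity 3/20 on a 20+20 test set are
expressible. Across-fold summaries use the sample (n−1) standard
deviation; report tables round half-up to two decimals.
`implied_confusion` inverts printed sensitivity/specificity pairs on a
known set layout back to integer counts and verifies round-trip
consistency.

Fold assignment is subject-disjoint and class-stratified (round-robin
deal after a seeded shuffle: per-fold class counts within one of
balance). Leakage guards assert on every run that train/validation/test
subject sets are pairwise disjoint and that augmented items derive only
from training subjects; violations raise, they are never warnings.

## Problem sizes in the test suite

Statistical calibration runs 5-fold CV on 20+20-subject cohorts with
one 2 s recording per subject and at most 12 training epochs: large
enough for a stable subject-level estimate (40 subjects ⇒ 95% binomial
chance band ≈ [0.35, 0.65]) and for the CNN to converge on the default
class effects, while keeping the whole suite around ten minutes on one
CPU. The augmentation-robustness check uses deliberately harder
conditions (8+8 subjects, 1 s recordings, half-sized deficits, 6
epochs, 5 seeds) and asserts only that block cut-and-paste augmentation
does not catastrophically reduce CV accuracy (mean shortfall ≤ 0.02);
the size of any *gain* from augmentation is data-dependent and is not
asserted.

## Known limitations

* The synthetic task is far easier than real pathological-speech
  classification; absolute accuracies here do not transfer.
* Only class labels are stratified (not sex or age, which the generator
  does not model).
* The NumPy trainer is single-threaded-friendly but slow compared to a
  GPU framework; cohort sizes beyond a few hundred subjects are
  impractical.
* Probabilities are uncalibrated; the 0.5 threshold is a convention.
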