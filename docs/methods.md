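# Methods

This note documents the models, conventions and design choices behind
`readmood`, in the order data flows through the pipeline.

## Problem setting

The package implements a screening pipeline for major depressive disorder
(MDD) from *text-dependent read speech*: participants read a fixed script
(a sustained vowel, digits, or a standard passage) into a smartphone
microphone, and a classifier decides MDD vs healthy control (HC) from the
acoustics alone. Read speech removes linguistic variability, so the
discriminative signal is prosodic and spectral: depressed speech tends to
be more monotonous — less pitch movement, less spectral variability —
than control speech. Two model families are compared on identical
speaker-independent splits: a compact 2-D CNN over log-Mel spectrogram
patches, and classical classifiers over per-utterance MFCC statistics.

## Synthetic cohort generator

Clinical speech corpora of this kind are private, so the package ships a
seeded generator whose output has the acoustic structure the analysis
depends on, without being speech. Each utterance is a source-filter
render:

* **Source** — a sawtooth wave whose fundamental follows a mean-reverting
  AR(1) random walk around `f0_mean` (default 140 Hz), updated every
  100 ms with stationary SD `f0_wander_sd` and a correlation time of
  roughly 10 s (ρ = 0.99 per step) — slow, prosody-like drift rather
  than jitter. Utterances much shorter than the correlation time
  express only part of the stationary variability, so class contrasts
  are strongest on the long passage task.
* **Filter** — three resonators (centers 500/1500/2500 Hz, bandwidths
  80/120/180 Hz) whose center frequencies drift as independent AR(1)
  walks with stationary SD `formant_wander_sd`, applied block-wise with
  filter-state carry-over.
* **Amplitude** — a slow sinusoidal modulation (depth 0.15, 1.5–3.5 Hz)
  times a fixed 4 Hz syllabic rhythm, so MFCC trajectories are
  non-trivial even within one class.
* **Silences** — Poisson-placed pauses (`pause_rate` per 10 s, at least
  one on long utterances) of 0.3–0.7 s with 20 ms cosine ramps, plus a
  leading noise-only head of 0.6 s. The head exceeds the 0.5 s noise
  profile window used downstream, so the noise gate always sees pure
  noise.
* **Noise** — stationary white background at `noise_floor_db`
  (default −60 dBFS RMS, a quiet-room figure; the recording protocol the
  generator emulates does not characterize its rooms, so this is a free
  parameter rather than a calibrated one).

**Class contrast.** The two classes share every parameter except the two
wander SDs. The depressed-like class keeps the base values
(`f0_wander_sd` 2 Hz, `formant_wander_sd` 15 Hz); the control-like class
gets `2 + 3·g` Hz and `15 + 30·g` Hz, where `g` is `variability_gap`.
At `g = 0` the classes are generatively identical (a null cohort for
calibration checks); increasing `g` monotonically widens the group
difference in spectral variability, mirroring the monotonous-speech
phenomenology. The default task durations (vowel 14 s, digit 15 s,
passage 80 s, with SDs 4.1/4.9/12.7 s) sit midway between typical
per-task speech times of the two groups in cohorts of this design,
where depressed readers take noticeably longer on the passage.

Determinism: one root seed; each (participant, task) stream is spawned by
fixed hashing of `(root, participant index, task index)`, so cohorts are
bit-reproducible and insensitive to generation order.

What the generator does **not** emulate: phonetic content, formant
dynamics of real articulation, microphone/room coloration,
non-stationary noise, and any correlate of depression other than reduced
prosodic/spectral variability. Passing tests therefore demonstrate that
the pipeline *recovers a variability contrast when one exists and finds
nothing when none exists* — not clinical validity on real speech.

## Preprocessing

1. **Spectral gating** (`reduce_noise`): one-sided STFT (Hann 1024,
   hop 512, no center padding). The frames lying wholly inside the first
   0.5 s give per-frequency mean and SD of log-magnitude; the gate
   threshold is mean + 1.5 SD. A binary keep-mask is smoothed with a
   3 (freq) × 5 (time) moving average and multiplied into the complex
   STFT; weighted overlap-add resynthesizes a waveform of identical
   length. The overlap-add envelope is clamped below 0.25 so the
   half-window signal edges, where the true envelope vanishes, are
   attenuated instead of amplified; interior samples divide exactly.
2. **Voice activity detection** (`detect_voice`): 30 ms frames every
   10 ms; a frame is speech if its RMS exceeds the 5th-percentile frame
   level by 10 dB *or* exceeds −35 dBFS outright (the absolute branch
   covers signals with no quiet floor at all). Speech runs separated by
   ≤ 200 ms merge; runs < 100 ms drop.
3. **Trimming**: speech spans are concatenated in order. Recordings with
   under 2 s of detected speech are flagged low-quality and excluded by
   the harness; the threshold operationalizes an exclusion rule whose
   criterion is otherwise unspecified, and is configurable.

## Log-Mel segmentation

STFT: Hann 1024 / hop 512 (≈ 23 ms at 50% overlap at 44.1 kHz), no
center padding, so an `N`-sample input yields exactly
`1 + ⌊(N − 1024)/512⌋` frames. Filterbank: 64 triangular filters with
centers equally spaced on the HTK mel scale
`mel(f) = 2595·log10(1 + f/700)`, peak height 1. Power is expressed in
dB with the floor 80 dB below the maximum; the dB reference never drops
below unit power, so digital silence lands exactly on the −80 dB floor
rather than being renormalized to 0 dB.

Segmentation cuts 64×200 patches (≈ 2.33 s) every 100 frames (50%
overlap). Each patch is re-referenced to its own maximum (peak 0 dB).
A final remainder window is emitted only when it holds at least 100 real
frames *and* extends past the span already covered by full windows; its
tail is padded at −80 dB. This rule reproduces the closed-form count
`⌊(n − 200)/100⌋ + 1 (+1 for a padded remainder)` and avoids emitting a
window that duplicates already-covered frames.

## SpecAugment expansion

Training partitions are expanded exactly 4×: raw, time-masked,
frequency-masked, and jointly masked copies. A frequency mask blanks
`f ~ U{0..F}` consecutive bands starting at `f0 ~ U{0..64−f}`; a time
mask blanks `t ~ U{0..W}` frames at `t0 ~ U{0..200−t}`. The maxima
default to `F = 8` of 64 bands and `W = 20` of 200 frames — the original
SpecAugment proportions scaled to this input size, since the masking
formulas fix the distributions but not the maxima. Masked cells take the
−80 dB floor of the max-referenced patch. One mask per axis per copy.
Validation and test segments are never augmented (enforced in the
harness and tagged in segment provenance).

## The CNN

Input 64×200×1, per-segment z-scored (identically at train and
inference). Four blocks of 3×3 convolution (16, 32, 64, 32 channels,
same padding) + ReLU + 2×2 max-pooling; then flatten → dense 128 → ReLU
→ dropout 0.5 → dense 64 → ReLU → dropout 0.5 → dense 1 → sigmoid.
Loss is binary cross-entropy (forced by the sigmoid head), optimizer
Adam at a fixed 1e-3, batch 32, up to 20 epochs with early stopping on
validation accuracy (default patience 5) and best-weight restoration.

Two pooling-stride readings are implemented. The default, stride (2, 2)
on both axes, shrinks the maps to 4×12 and yields 246,817 parameters —
consistent with the design goal of a small model. The alternative
`literal` mode uses stride (1, 2) (stride 1 on the mel axis); it is
selectable and covered by the parameter-count oracle but is not the
default, because four stride-1 poolings leave a 60×12 map and a 3 M
parameter dense layer, at odds with the small-model intent.

The implementation is pure NumPy, channels-last: convolutions are im2col
GEMMs over stacked kernel shifts, the input gradient is the transposed
GEMM scattered back through the same shifts, max-pool argmaxes are
tracked exactly (ties break toward the top-left element), and Adam is
the standard bias-corrected form. Backprop is verified against central
finite differences; inference is deterministic.

## Classical baselines

Per (trimmed) recording: MFCCs from 25 ms Hamming frames at 50% overlap,
power spectrum zero-padded to the next power of two, 26 triangular mel
filters, floored natural log, orthonormal DCT-II, coefficients 1–12 kept
(c0 excluded, making the features invariant to overall gain). The
utterance vector is the 24-dim concatenation of per-coefficient means
and SDs (ddof = 1), computed over the whole trimmed utterance — the
natural unit for one-vector-per-speaker classifiers; per-window
statistics, if wanted, are obtained by slicing the MFCC matrix and
summarizing each slice. "MFCC3" is the third kept coefficient; its
*variability* is the mean-centered trajectory, summarized by its SD.

Classifiers: linear SVM (C = 1), LDA, kNN (k = 5, Euclidean), random
forest (100 trees, Gini). SVM/LDA/kNN see z-scored features whose
scaler is fitted on the training fold only; the forest, scale-invariant,
is fitted raw. Externally extracted feature tables (eGeMAPS/COMPARE
style CSVs) can be ingested in place of MFCC vectors; their extraction
is out of scope.

## Evaluation protocol

Splits are at the participant level: train = ⌊0.8 N⌋, remainder halved
between validation and test (odd remainder favors validation),
stratified by class via largest-remainder allocation (each partition's
class count within one participant of proportionality). "10-fold
cross-validation" is realized as ten independently seeded resamples of
this 80/10/10 split — reconciling a fixed three-way split with ten folds
— so every fold is speaker-disjoint by construction; at N = 318 with
153/165 classes each fold is exactly 254/32/32.

The CNN is scored at two levels: per segment, and per participant after
averaging the participant's segment probabilities (label 1 iff the mean
is ≥ 0.5). Baselines operate on one vector per recording, i.e.
participant level directly. Metrics: accuracy, precision, recall,
F1 = 2PR/(P+R), ROC by threshold sweep with trapezoid AUC (equal to the
normalized Mann-Whitney U; asserted in tests). MDD is the positive
class; macro-averaged precision/recall are reported alongside.
Zero-division metrics report 0 with a flag; a single-class truth vector
omits AUC with a flag. Fold failures are isolated, counted and reported
without aborting the run.

## Problem sizes in the shipped checks

Preprocessing, feature extraction and segmentation run once per
recording and are shared across folds. To keep the end-to-end checks
tractable on a single CPU, the harness caps segments per recording
(evenly spaced): the signal-recovery check uses a 60-participant passage
cohort at `variability_gap = 2` with 10 folds, 5 training and 8
evaluation segments per recording, and 6 epochs; the null-cohort check
uses 30 participants on the vowel task at gap 0 with 2 epochs; the
reproduction script runs the same contrast cohort with 4 folds and 8
epochs. These caps and epoch counts are problem-size choices,
not tuning knobs: class-contrast parameters, thresholds and seeds are
fixed independently of them.

## Numerical choices and degenerate inputs

* dB floors: −80 dB re max (log-Mel), `1e-10` before the MFCC log.
* All-zero audio: gating returns zeros; VAD returns no intervals;
  log-Mel returns the floor everywhere.
* The STFT used for gating requires hop | window; reconstruction is
  exact away from the half-window edges.
* Mask draws, fold splits, weight init, dropout and shuffling all derive
  from explicit integer seeds; per-fold seeds are spawned from the run
  seed.
* Pooling with odd spatial extent truncates the trailing row/column
  (floor semantics), matching the closed-form size arithmetic used in
  the parameter-count oracle.

## Known limitations

* The generator's contrast is a single variability axis; real depressed
  speech differs along many correlated axes (timing, voice quality,
  articulation) that are not modeled.
* The energy VAD assumes a quiet, stationary background; it is not a
  substitute for a trained VAD under real noise.
* The NumPy CNN is single-threaded and sized for desk-scale cohorts;
  training hundreds of participants with uncapped segments would call
  for a GPU framework.
* PHQ-9 severity regression, pretrained-backbone transfer and external
  benchmark corpora are out of scope.
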