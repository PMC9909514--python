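# readmood

Depression screening from smartphone **read speech**. People with major
depressive disorder (MDD) tend to read a fixed script with flatter
prosody and less spectral movement than healthy controls (HC);
`readmood` implements a complete, tested pipeline that turns this
observation into a classifier and evaluates it honestly:

1. **Cleanup** — stationary spectral gating against the first 0.5 s of
   each recording (protocol-guaranteed noise-only), then an energy-based
   voice activity detector that strips silences.
2. **Representation** — 64-band log-Mel spectrograms (`n_fft=1024`,
   `hop=512` at 44.1 kHz), cut into 64×200 patches with 50% overlap.
3. **Augmentation** — SpecAugment-style frequency and time masking,
   expanding every training set exactly 4× (raw + time-masked +
   frequency-masked + jointly masked).
4. **Models** — a compact CNN (four 3×3 conv blocks of 16/32/64/32
   channels with 2×2 max-pooling, dense 128→64 head with 0.5 dropout,
   sigmoid output; ~247 k parameters; Adam 1e-3, batch 32, early
   stopping), implemented in pure NumPy with exact backprop, against
   four classical baselines (linear SVM C=1, LDA, kNN k=5, random
   forest with 100 trees) over 24-dim MFCC mean/SD utterance vectors.
5. **Evaluation** — participant-independent 80/10/10 splits (exactly
   254/32/32 at the reference cohort size of 318), ten seeded resamples
   ("folds"), metrics at both segment and participant level (segment
   probabilities averaged per speaker): accuracy, precision, recall,
   F1 = 2PR/(P+R), trapezoid AUC.

Because clinical recordings of this kind are private, the package ships
a seeded **synthetic cohort generator**: source-filter utterances whose
pitch and formants wander more for control-like voices than for
MDD-like ones (`variability_gap` scales the contrast; 0 gives a null
cohort). It exists so every stage — including the end-to-end claim
"the pipeline recovers a variability contrast when one exists and stays
at chance when none does" — is testable. See `docs/methods.md` for the
model details and what synthetic results do and do not show.

## Worked example

```python
from readmood import (CohortConfig, TaskSpec, generate_cohort,
                      ExperimentConfig, TrainConfig, run_experiment)

cohort = CohortConfig(
    n_participants=16,
    tasks={"passage": TaskSpec("passage", 30.0, 4.0)},
    variability_gap=2.0,     # strong monotony contrast
    seed=7)
recordings, manifest = generate_cohort(cohort)

config = ExperimentConfig(
    models=("cnn", "rf"), n_folds=3, seed=7,
    train=TrainConfig(epochs=4, patience=2),
    max_train_segments=5, max_eval_segments=8)
report = run_experiment(recordings, config)
agg = report.aggregates()
print(agg[agg.level == "participant"]
      [["model", "accuracy_mean", "accuracy_std", "auc_mean"]]
      .to_string(index=False))
```

Output:

```
model  accuracy_mean  accuracy_std  auc_mean
  cnn            0.5           0.0       1.0
   rf            1.0           0.0       1.0
```

Each row is the mean (and SD) over three speaker-disjoint folds of
participant-level accuracy and AUC on held-out speakers. On this small
demo the random forest over MFCC statistics separates the classes
perfectly. The CNN — trained for only four epochs on twelve speakers —
already *ranks* every held-out speaker correctly (AUC 1.0) but its
probabilities have not yet crossed the 0.5 decision threshold, a
typical small-sample calibration artifact; at the scale the test suite
exercises (60 participants, 6 epochs) it reaches ≥ 0.90 accuracy with
AUC ≥ 0.95.

A command-line workflow wraps the same library (`readmood simulate`,
`preprocess`, `featurize`, `run`, `report`), driven by a single YAML
config; every run writes its resolved configuration and hash next to
its outputs.

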