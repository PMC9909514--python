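"""Speaker-independent evaluation: splits, metrics, experiment runner.

Splitting follows a participant-level 80/10/10 convention: with N
participants the training set holds floor(0.8*N) and the remainder is
divided equally between validation and test (an odd remainder favors
validation), stratified by class.  "10-fold cross-validation" is realized
as 10 independently seeded resamples of that split, so no speaker ever
appears in more than one partition of any fold.  At N=318 with a 153/165
class balance this reproduces a 254/32/32 split exactly.

The experiment runner executes, per fold x task x model, the full chain
preprocess -> features/segments -> (SpecAugment on the training partition
only) -> fit -> test, and reports accuracy, precision, recall, F1 and
trapezoid AUC at both the segment level and the participant level
(segment probabilities averaged per speaker, threshold 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .augment import AugmentConfig, specaugment_expand
from .baselines import BASELINE_KINDS, BaselineSpec, fit_baseline, \
    predict_baseline
from .cnn import CnnArchitecture, TrainConfig, build_cnn, predict_segments, \
    segments_to_array, train_cnn
from .features import MfccConfig, extract_features
from .preprocess import preprocess_recording
from .spectro import SpectroConfig, segments_from_recording
from .synth import AudioRecording

__all__ = [
    "SplitPlan",
    "ExperimentConfig",
    "EvaluationReport",
    "make_splits",
    "aggregate_to_participant",
    "compute_metrics",
    "run_experiment",
]


@dataclass
class SplitPlan:
    fold_index: int
    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset
    seed: int

    def __post_init__(self) -> None:
        sets = (self.train_ids, self.val_ids, self.test_ids)
        total = sum(len(s) for s in sets)
        if len(self.train_ids | self.val_ids | self.test_ids) != total:
            raise ValueError("split partitions must be pairwise disjoint")


def _largest_remainder(quotas: dict, caps: dict, total: int) -> dict:
    """Integer allocation by largest fractional remainder, capped."""
    base = {c: min(caps[c], int(math.floor(q))) for c, q in quotas.items()}
    leftover = total - sum(base.values())
    order = sorted(quotas, key=lambda c: quotas[c] - math.floor(quotas[c]),
                   reverse=True)
    i = 0
    while leftover > 0:
        c = order[i % len(order)]
        if base[c] < caps[c]:
            base[c] += 1
            leftover -= 1
        i += 1
        if i > 10 * len(order) and leftover > 0:
            raise ValueError("cannot satisfy allocation under caps")
    return base


def partition_sizes(n: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
                    ) -> tuple[int, int, int]:
    """(train, val, test) sizes: floor train, remainder split val/test."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n_train = int(math.floor(ratios[0] * n))
    rem = n - n_train
    n_val = int(math.ceil(rem * ratios[1] / (ratios[1] + ratios[2])))
    return n_train, n_val, rem - n_val


def make_splits(manifest: pd.DataFrame, n_folds: int = 10,
                ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                stratified: bool = True, seed: int = 0) -> list[SplitPlan]:
    """Independently seeded participant-level stratified splits."""
    parts = (manifest[["participant_id", "group"]]
             .drop_duplicates("participant_id"))
    n = len(parts)
    if n < 3:
        raise ValueError("need at least 3 participants")
    n_train, n_val, n_test = partition_sizes(n, ratios)
    by_class = {g: df["participant_id"].to_numpy()
                for g, df in parts.groupby("group")}
    if stratified and any(len(v) < 3 for v in by_class.values()):
        raise ValueError("every class needs at least 3 participants")

    plans = []
    for fold in range(n_folds):
        fold_seed = int(np.random.SeedSequence(
            seed, spawn_key=(fold,)).generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(fold_seed)
        train, val, test = [], [], []
        if stratified:
            shuffled = {c: rng.permutation(ids)
                        for c, ids in by_class.items()}
            counts = {c: len(ids) for c, ids in by_class.items()}
            tr_alloc = _largest_remainder(
                {c: n_train * counts[c] / n for c in counts}, counts, n_train)
            rem_counts = {c: counts[c] - tr_alloc[c] for c in counts}
            rem_total = sum(rem_counts.values())
            va_alloc = _largest_remainder(
                {c: n_val * rem_counts[c] / rem_total for c in counts},
                rem_counts, n_val)
            for c, ids in shuffled.items():
                a, b = tr_alloc[c], tr_alloc[c] + va_alloc[c]
                train.extend(ids[:a])
                val.extend(ids[a:b])
                test.extend(ids[b:])
        else:
            ids = rng.permutation(parts["participant_id"].to_numpy())
            train = ids[:n_train]
            val = ids[n_train:n_train + n_val]
            test = ids[n_train + n_val:]
        plans.append(SplitPlan(fold, frozenset(train), frozenset(val),
                               frozenset(test), fold_seed))
    return plans


def aggregate_to_participant(participant_ids, probs
                             ) -> pd.DataFrame:
    """Mean segment probability per participant; label = mean >= 0.5.

    Accepts parallel arrays of participant ids and segment probabilities;
    raises on empty input.  Permutation-invariant by construction.
    """
    participant_ids = np.asarray(participant_ids)
    probs = np.asarray(probs, float)
    if len(participant_ids) == 0:
        raise ValueError("no segment probabilities to aggregate")
    if len(participant_ids) != len(probs):
        raise ValueError("id/probability length mismatch")
    df = (pd.DataFrame({"participant_id": participant_ids, "prob": probs})
          .groupby("participant_id", sort=True)["prob"].mean()
          .reset_index())
    df["pred"] = (df["prob"] >= 0.5).astype(int)
    return df


@dataclass
class MetricRecord:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    precision_macro: float
    recall_macro: float
    confusion: np.ndarray
    roc: tuple[np.ndarray, np.ndarray] | None
    flags: list[str] = field(default_factory=list)

    def scalars(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
                "precision_macro": self.precision_macro,
                "recall_macro": self.recall_macro}


def compute_metrics(y_true, y_pred, y_score=None) -> MetricRecord:
    """Binary metrics with MDD as the positive class.

    F1 is the harmonic mean 2PR/(P+R); ROC is a threshold sweep of the
    scores with trapezoid-rule AUC.  Zero-division metrics report 0 with
    a warning flag; a single-class truth vector omits the AUC with a flag.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    flags: list[str] = []
    acc = float(skm.accuracy_score(y_true, y_pred))
    prec = float(skm.precision_score(y_true, y_pred, zero_division=0))
    rec = float(skm.recall_score(y_true, y_pred, zero_division=0))
    f1 = float(skm.f1_score(y_true, y_pred, zero_division=0))
    if y_pred.sum() == 0 or y_true.sum() == 0:
        flags.append("zero_division")
    prec_m = float(skm.precision_score(y_true, y_pred, average="macro",
                                       zero_division=0))
    rec_m = float(skm.recall_score(y_true, y_pred, average="macro",
                                   zero_division=0))
    conf = skm.confusion_matrix(y_true, y_pred, labels=[0, 1])
    auc = roc = None
    if y_score is not None:
        if len(np.unique(y_true)) < 2:
            flags.append("auc_omitted_single_class")
        else:
            fpr, tpr, _ = skm.roc_curve(y_true, np.asarray(y_score, float))
            auc = float(skm.auc(fpr, tpr))
            roc = (fpr, tpr)
    return MetricRecord(acc, prec, rec, f1, auc, prec_m, rec_m, conf,
                        roc, flags)


@dataclass
class ExperimentConfig:
    """Everything the experiment runner needs beyond the cohort itself."""

    tasks: tuple[str, ...] | None = None       # None -> all tasks present
    models: tuple[str, ...] = ("cnn",) + BASELINE_KINDS
    n_folds: int = 10
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    stratified: bool = True
    seed: int = 0
    spectro: SpectroConfig = field(default_factory=SpectroConfig)
    arch: CnnArchitecture = field(default_factory=CnnArchitecture)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment_F: int = 8
    augment_W: int = 20
    preprocess_audio: bool = True
    min_total_speech_s: float = 2.0
    # problem-size knobs: cap segments per recording (evenly spaced)
    max_train_segments: int | None = None
    max_eval_segments: int | None = None


@dataclass
class EvaluationReport:
    """Fold-level metric rows plus aggregation helpers and provenance."""

    rows: pd.DataFrame
    failures: list[dict]
    provenance: dict
    roc_points: dict = field(default_factory=dict)
    histories: dict = field(default_factory=dict)  # (task, fold) -> dict

    _METRICS = ("accuracy", "precision", "recall", "f1", "auc")

    def aggregates(self) -> pd.DataFrame:
        """Mean and SD over folds per (task, model, level)."""
        g = self.rows.groupby(["task", "model", "level"])[list(self._METRICS)]
        agg = g.agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        return agg.reset_index()

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _cap_segments(segments, cap):
    if cap is None or len(segments) <= cap:
        return segments
    idx = np.linspace(0, len(segments) - 1, cap).round().astype(int)
    return [segments[i] for i in np.unique(idx)]


def _gather(seg_by_pid, ids, cap):
    out = []
    for pid in sorted(ids):
        out.extend(_cap_segments(seg_by_pid[pid], cap))
    return out


def _run_cnn_fold(plan, seg_by_pid, labels, config):
    train_segs = _gather(seg_by_pid, plan.train_ids,
                         config.max_train_segments)
    val_segs = _gather(seg_by_pid, plan.val_ids, config.max_eval_segments)
    test_segs = _gather(seg_by_pid, plan.test_ids, config.max_eval_segments)
    assert all(s.augmented is None for s in val_segs + test_segs)
    aug = specaugment_expand(
        train_segs, AugmentConfig(F=config.augment_F, W=config.augment_W,
                                  seed=plan.seed))
    x_tr, y_tr = segments_to_array(aug)
    x_va, y_va = segments_to_array(val_segs)
    model = build_cnn(config.arch, seed=plan.seed)
    tc = config.train
    history = train_cnn(model, x_tr, y_tr, x_va, y_va,
                        TrainConfig(tc.epochs, tc.batch_size,
                                    tc.learning_rate, tc.patience,
                                    plan.seed))
    probs = predict_segments(model, test_segs)
    seg_true = np.array([s.label for s in test_segs])
    seg_metrics = compute_metrics(seg_true, (probs >= 0.5).astype(int), probs)
    part = aggregate_to_participant([s.participant_id for s in test_segs],
                                    probs)
    part_true = part["participant_id"].map(labels).to_numpy()
    part_metrics = compute_metrics(part_true, part["pred"].to_numpy(),
                                   part["prob"].to_numpy())
    return seg_metrics, part_metrics, history


def run_experiment(recordings: list[AudioRecording],
                   config: ExperimentConfig = ExperimentConfig()
                   ) -> EvaluationReport:
    """Cross-validated depression-detection experiment on a cohort.

    Preprocessing, feature extraction and segmentation run once per
    recording; each fold then re-splits participants, expands only its
    training segments with SpecAugment, trains the CNN and the requested
    baselines, and evaluates on the fold's held-out speakers.  Stage
    failures mark the fold as failed and the run continues.
    """
    tasks = (config.tasks if config.tasks is not None
             else tuple(sorted({r.task for r in recordings})))
    rows, failures = [], []
    roc_points = {}
    histories = {}
    preprocess_log = []
    for task in tasks:
        task_recs = [r for r in recordings if r.task == task]
        seg_by_pid: dict[str, list] = {}
        feats_by_pid: dict[str, object] = {}
        labels: dict[str, int] = {}
        for rec in task_recs:
            if config.preprocess_audio:
                clean, log = preprocess_recording(
                    rec, min_total_speech_s=config.min_total_speech_s)
                preprocess_log.append(log)
                if log["dropped"]:
                    continue
            else:
                clean = rec
            if len(clean.samples) < config.spectro.segment_samples // 2:
                continue
            segs = segments_from_recording(clean, config.spectro)
            if not segs:
                continue
            mfcc_cfg = MfccConfig(sample_rate=clean.sample_rate)
            feats_by_pid[rec.participant_id] = extract_features(
                clean, mfcc_cfg)
            seg_by_pid[rec.participant_id] = segs
            labels[rec.participant_id] = rec.label
        retained = pd.DataFrame(
            {"participant_id": list(labels),
             "group": ["MDD" if v else "HC" for v in labels.values()]})
        plans = make_splits(retained, config.n_folds, config.ratios,
                            config.stratified, config.seed)
        for plan in plans:
            if "cnn" in config.models:
                try:
                    seg_m, part_m, history = _run_cnn_fold(
                        plan, seg_by_pid, labels, config)
                    histories[(task, plan.fold_index)] = history
                    for level, m in (("segment", seg_m),
                                     ("participant", part_m)):
                        rows.append({"task": task, "model": "cnn",
                                     "fold": plan.fold_index, "level": level,
                                     **m.scalars(),
                                     "n_eval": int(m.confusion.sum())})
                    if part_m.roc is not None:
                        roc_points[(task, "cnn", plan.fold_index)] = part_m.roc
                except Exception as exc:  # noqa: BLE001 - fold isolation
                    failures.append({"task": task, "model": "cnn",
                                     "fold": plan.fold_index,
                                     "error": repr(exc)})
            base_kinds = [m for m in config.models if m in BASELINE_KINDS]
            if base_kinds:
                tr_ids = sorted(plan.train_ids)
                te_ids = sorted(plan.test_ids)
                X_tr = np.stack([feats_by_pid[p].vector for p in tr_ids])
                y_tr = np.array([labels[p] for p in tr_ids])
                X_te = np.stack([feats_by_pid[p].vector for p in te_ids])
                y_te = np.array([labels[p] for p in te_ids])
            for kind in base_kinds:
                try:
                    est = fit_baseline(BaselineSpec(kind, seed=plan.seed),
                                       X_tr, y_tr)
                    y_pred, scores = predict_baseline(est, X_te)
                    m = compute_metrics(y_te, y_pred, scores)
                    rows.append({"task": task, "model": kind,
                                 "fold": plan.fold_index,
                                 "level": "participant", **m.scalars(),
                                 "n_eval": int(m.confusion.sum())})
                    if m.roc is not None:
                        roc_points[(task, kind, plan.fold_index)] = m.roc
                except Exception as exc:  # noqa: BLE001
                    failures.append({"task": task, "model": kind,
                                     "fold": plan.fold_index,
                                     "error": repr(exc)})
    provenance = {
        "seed": config.seed,
        "n_folds": config.n_folds,
        "tasks": list(tasks),
        "models": list(config.models),
        "preprocess_log": preprocess_log,
        "n_failures": len(failures),
    }
    return EvaluationReport(pd.DataFrame(rows), failures, provenance,
                            roc_points, histories)
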