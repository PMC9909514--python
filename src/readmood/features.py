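"""Classical acoustic features: MFCCs, utterance statistics, variability.

Per frame (25 ms Hamming window, 50% overlap): power spectrum, 26-filter
mel bank, natural log of the filter energies (floored), orthonormal
type-II DCT, coefficients 1..12 kept (the energy coefficient c0 is
excluded, which makes the kept coefficients invariant to overall
amplitude scaling).  An utterance is summarized by the mean and the
sample SD of each coefficient — a 24-dimensional vector — and the
"variability" of a single coefficient (MFCC3 by convention, i.e. the
third kept coefficient) is its mean-centered trajectory plus that
trajectory's SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dct

from .spectro import mel_filterbank
from .synth import AudioRecording

__all__ = [
    "MfccConfig",
    "UtteranceFeatures",
    "VariabilityTrace",
    "mfcc",
    "summarize",
    "variability_trace",
    "extract_features",
    "load_external_features",
]

LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class MfccConfig:
    frame_ms: float = 25.0
    overlap: float = 0.5
    n_filters: int = 26
    n_coeffs: int = 12            # keep coefficients 1..n_coeffs
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")
        if self.n_coeffs >= self.n_filters:
            raise ValueError("kept coefficients must be < n_filters")
        if self.frame_samples < 2:
            raise ValueError("frame shorter than 2 samples")

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_ms / 1000.0 * self.sample_rate))

    @property
    def hop_samples(self) -> int:
        return max(1, int(round(self.frame_samples * (1.0 - self.overlap))))

    @property
    def n_fft(self) -> int:
        return 1 << int(np.ceil(np.log2(self.frame_samples)))


@dataclass
class UtteranceFeatures:
    """24-dim (mean_1..12, sd_1..12) summary of one recording."""

    participant_id: str
    task: str
    label: int
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("feature vector must be finite")


@dataclass
class VariabilityTrace:
    """Mean-centered trajectory of one coefficient and its SD summary."""

    participant_id: str
    label: int
    coeff_index: int
    trace: np.ndarray
    summary: float = field(init=False)

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, float)
        self.summary = float(np.std(self.trace, ddof=1))


def mfcc(recording: AudioRecording,
         config: MfccConfig | None = None) -> np.ndarray:
    """Frame-wise MFCC matrix of shape ``(n_frames, n_coeffs)``.

    Hamming-windowed (symmetric) power spectrum, zero-padded to the next
    power of two; filter energies pass through a floored natural log and
    an orthonormal DCT-II; coefficient 0 is dropped.
    """
    if config is None:
        config = MfccConfig(sample_rate=recording.sample_rate)
    if config.sample_rate != recording.sample_rate:
        raise ValueError("config sample rate does not match the recording")
    x = np.asarray(recording.samples, float)
    frame, hop = config.frame_samples, config.hop_samples
    if len(x) < frame:
        raise ValueError("recording shorter than one analysis frame")
    frames = np.lib.stride_tricks.sliding_window_view(x, frame)[::hop]
    window = np.hamming(frame)
    spec = np.abs(np.fft.rfft(frames * window, n=config.n_fft, axis=1)) ** 2
    fb = mel_filterbank(config.sample_rate, config.n_fft, config.n_filters)
    energies = spec @ fb.T                       # (n_frames, n_filters)
    logs = np.log(np.maximum(energies, LOG_FLOOR))
    cepstra = dct(logs, type=2, norm="ortho", axis=1)
    return cepstra[:, 1:config.n_coeffs + 1]


def summarize(mfcc_series: np.ndarray,
              participant_id: str = "", task: str = "",
              label: int = 0) -> UtteranceFeatures:
    """Concatenate per-coefficient means and sample SDs (n-1 denominator)."""
    series = np.asarray(mfcc_series, float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("need at least 2 frames to summarize")
    vector = np.concatenate([series.mean(axis=0), series.std(axis=0, ddof=1)])
    return UtteranceFeatures(participant_id, task, label, vector)


def variability_trace(mfcc_series: np.ndarray, coeff: int = 3,
                      participant_id: str = "",
                      label: int = 0) -> VariabilityTrace:
    """Mean-centered trajectory of one kept coefficient (1-based index)."""
    series = np.asarray(mfcc_series, float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not (1 <= coeff <= series.shape[1]):
        raise ValueError(f"coefficient index must lie in 1..{series.shape[1]}")
    c = series[:, coeff - 1]
    return VariabilityTrace(participant_id, label, coeff, c - c.mean())


def extract_features(recording: AudioRecording,
                     config: MfccConfig | None = None) -> UtteranceFeatures:
    """MFCC extraction + summarization for one (trimmed) recording."""
    series = mfcc(recording, config)
    return summarize(series, recording.participant_id, recording.task,
                     recording.label)


def load_external_features(table_path,
                           manifest: pd.DataFrame | None = None
                           ) -> list[UtteranceFeatures]:
    """Ingest an externally extracted feature table (openSMILE-style CSV).

    The table must carry ``participant_id`` and ``task`` columns plus an
    arbitrary but fixed number of numeric feature columns.  When a
    manifest is given, labels are joined on (participant_id, task);
    otherwise labels default to 0.
    """
    df = pd.read_csv(table_path, dtype={"participant_id": str})
    for col in ("participant_id", "task"):
        if col not in df.columns:
            raise ValueError(f"feature table is missing the {col!r} column")
    feature_cols = [c for c in df.columns
                    if c not in ("participant_id", "task", "label")]
    if not feature_cols:
        raise ValueError("feature table has no feature columns")
    labels = {}
    if manifest is not None:
        labels = {(r.participant_id, r.task): (1 if r.group == "MDD" else 0)
                  for r in manifest.itertuples()}
    out = []
    for idx, row in df.iterrows():
        values = pd.to_numeric(row[feature_cols], errors="coerce").to_numpy()
        if np.any(~np.isfinite(values)):
            raise ValueError(f"non-numeric feature value in row {idx}")
        key = (row["participant_id"], row["task"])
        out.append(UtteranceFeatures(row["participant_id"], row["task"],
                                     labels.get(key, 0), values))
    return out
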