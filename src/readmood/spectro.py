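"""Log-Mel spectrograms and fixed-size segments for the CNN.

The classifier consumes image-like patches of ``n_mels x segment_frames``
(64 x 200 under defaults): a Hann-windowed power STFT without center
padding (so frame counts follow the closed form
``1 + floor((N - n_fft) / hop)``), projected onto triangular mel filters,
expressed in dB relative to the segment maximum with an -80 dB floor,
and cut into 50%-overlapping 200-frame windows.

The mel scale used is ``mel(f) = 2595 * log10(1 + f / 700)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .synth import AudioRecording

__all__ = [
    "SpectroConfig",
    "LogMelSegment",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "logmel",
    "segment",
    "segments_from_recording",
]

DB_FLOOR = -80.0


@dataclass(frozen=True)
class SpectroConfig:
    n_fft: int = 1024
    hop: int = 512
    n_mels: int = 64
    segment_frames: int = 200
    segment_hop_frames: int = 100
    fmin: float = 0.0
    fmax: float | None = None          # None -> sample_rate / 2
    pad_policy: str = "pad_if_half"    # or "drop"

    def __post_init__(self) -> None:
        if self.hop > self.n_fft:
            raise ValueError("hop must not exceed n_fft")
        if self.segment_hop_frames > self.segment_frames:
            raise ValueError("segment hop must not exceed segment length")
        if self.n_mels < 1:
            raise ValueError("need at least one mel band")
        if self.pad_policy not in ("pad_if_half", "drop"):
            raise ValueError("pad_policy must be 'pad_if_half' or 'drop'")

    @property
    def segment_samples(self) -> int:
        """Waveform samples that yield exactly ``segment_frames`` frames."""
        return (self.segment_frames - 1) * self.hop + self.n_fft


@dataclass
class LogMelSegment:
    """One fixed-size dB patch with provenance metadata."""

    values: np.ndarray                 # (n_mels, segment_frames), dB
    participant_id: str
    task: str
    segment_index: int
    label: int
    augmented: str | None = None       # None for raw, else mask description

    @property
    def source_id(self) -> tuple:
        return (self.participant_id, self.task, self.segment_index)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int,
                   fmin: float = 0.0,
                   fmax: float | None = None) -> np.ndarray:
    """Triangular filters, centers equally spaced on the mel scale.

    Returns an ``(n_mels, n_fft // 2 + 1)`` non-negative weight matrix
    (triangle peaks at 1).  Raises if the FFT resolution cannot separate
    adjacent filter centers.
    """
    fmax = sample_rate / 2.0 if fmax is None else fmax
    if not (0.0 <= fmin < fmax <= sample_rate / 2.0):
        raise ValueError("need 0 <= fmin < fmax <= sample_rate/2")
    n_bins = n_fft // 2 + 1
    breakpoints = mel_to_hz(
        np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    bin_freqs = np.linspace(0.0, sample_rate / 2.0, n_bins)
    center_bins = np.round(breakpoints / (sample_rate / n_fft)).astype(int)
    if len(np.unique(center_bins)) < len(center_bins):
        raise ValueError(
            "n_mels too large for the FFT resolution (duplicate centers)")
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, mid, hi = breakpoints[m], breakpoints[m + 1], breakpoints[m + 2]
        up = (bin_freqs - lo) / (mid - lo)
        down = (hi - bin_freqs) / (hi - mid)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def frame_signal(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Frames without center padding: ``1 + (len(x) - n_fft) // hop`` rows."""
    if len(x) < n_fft:
        raise ValueError("signal shorter than one analysis frame")
    return sliding_window_view(x, n_fft)[::hop]


def logmel(recording: AudioRecording,
           config: SpectroConfig = SpectroConfig()) -> np.ndarray:
    """Power STFT -> mel filterbank -> dB, floored 80 dB under the maximum.

    Cell values stay on the raw dB scale (so scaling the waveform shifts
    unfloored cells by the corresponding dB amount); the floor sits at
    ``max(db.max(), 0) - 80``, the reference never dropping below unit
    power, so digital silence lands exactly on ``DB_FLOOR``.  Per-segment
    max-referencing happens later, in :func:`segment`.
    """
    x = np.asarray(recording.samples, float)
    frames = frame_signal(x, config.n_fft, config.hop)
    win = signal.get_window("hann", config.n_fft, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    fb = mel_filterbank(recording.sample_rate, config.n_fft, config.n_mels,
                        config.fmin, config.fmax)
    mel = fb @ spec.T                              # (n_mels, n_frames)
    db = 10.0 * np.log10(np.maximum(mel, 1e-30))
    ref = max(db.max(), 0.0)
    return np.maximum(db, ref + DB_FLOOR)


def segment(spectrogram: np.ndarray,
            config: SpectroConfig = SpectroConfig(),
            participant_id: str = "",
            task: str = "",
            label: int = 0) -> list[LogMelSegment]:
    """Cut a spectrogram into fixed-size windows.

    Full windows start every ``segment_hop_frames``.  Under the
    ``pad_if_half`` policy one extra window is emitted at the next hop
    position when it would cover at least ``segment_frames / 2`` real
    frames *and* reach beyond the span already covered; its tail is
    padded with the dB floor.  Under ``drop`` the remainder is discarded.
    """
    if spectrogram.shape[0] != config.n_mels:
        raise ValueError("spectrogram row count does not match n_mels")
    n = spectrogram.shape[1]
    seg, hop = config.segment_frames, config.segment_hop_frames

    starts = list(range(0, n - seg + 1, hop)) if n >= seg else []
    covered = starts[-1] + seg if starts else 0
    windows: list[np.ndarray] = [spectrogram[:, s:s + seg] for s in starts]

    if config.pad_policy == "pad_if_half":
        nxt = starts[-1] + hop if starts else 0
        avail = n - nxt
        if avail >= seg / 2 and n > covered:
            windows.append(spectrogram[:, nxt:])

    out = []
    for i, w in enumerate(windows):
        # reference each window to its own maximum (0 dB peak per patch)
        vals = np.maximum(w - w.max(), DB_FLOOR).astype(np.float32)
        if vals.shape[1] < seg:
            pad = np.full((config.n_mels, seg), DB_FLOOR, dtype=np.float32)
            pad[:, :vals.shape[1]] = vals
            vals = pad
        out.append(LogMelSegment(np.ascontiguousarray(vals),
                                 participant_id, task, i, label))
    return out


def segments_from_recording(
    recording: AudioRecording,
    config: SpectroConfig = SpectroConfig(),
) -> list[LogMelSegment]:
    """Convenience chain: log-Mel then segmentation, metadata attached."""
    spec = logmel(recording, config)
    return segment(spec, config, recording.participant_id,
                   recording.task, recording.label)
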