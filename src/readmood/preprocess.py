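"""Audio cleanup before feature extraction.

Two stages, mirroring common practice for quiet-room speech recordings:

1. :func:`reduce_noise` — stationary spectral gating.  The first
   ``noise_profile_s`` seconds of every utterance are noise-only by
   recording protocol; their short-time spectrum gives a per-frequency
   gate threshold (mean + ``n_std``·SD in dB).  Time-frequency cells below
   threshold are attenuated through a smoothed soft mask and the waveform
   is resynthesized at identical length and sample rate.

2. :func:`detect_voice` / :func:`trim_to_speech` — an energy-based voice
   activity detector.  Frames whose RMS exceeds the 5th-percentile frame
   level by ``rel_threshold_db`` (or an absolute speech level, whichever
   admits more) are speech; nearby runs are merged, short blips dropped,
   and the recording is cut down to the concatenated speech spans.

Recordings whose detected speech is shorter than ``min_total_speech_s``
are flagged low-quality so the evaluation harness can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, signal

from .synth import AudioRecording

__all__ = [
    "SpeechIntervals",
    "reduce_noise",
    "detect_voice",
    "trim_to_speech",
    "preprocess_recording",
]

_EPS = 1e-12


@dataclass
class SpeechIntervals:
    """Ordered, non-overlapping half-open speech spans in seconds."""

    intervals: list[tuple[float, float]]

    @property
    def total_speech_s(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for s, e in self.intervals:
            if e <= s:
                raise ValueError("interval end must exceed start")
            if s < prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = e


def _stft(x: np.ndarray, win: np.ndarray, hop: int) -> np.ndarray:
    """Batch one-sided STFT without center padding: (n_bins, n_frames)."""
    frames = sliding_window_view(x, len(win))[::hop]
    return np.fft.rfft(frames * win, axis=1).T


def _istft(S: np.ndarray, win: np.ndarray, hop: int, n: int) -> np.ndarray:
    """Weighted overlap-add inverse of :func:`_stft` (length-n output).

    Requires ``hop`` to divide the window length, so that every stride
    class of frames tiles the signal without internal overlap and the
    overlap-add reduces to vectorized slice additions.
    """
    if len(win) % hop:
        raise ValueError("hop must divide the window length")
    frames = np.fft.irfft(S.T, n=len(win), axis=1) * win
    n_frames = frames.shape[0]
    total = (n_frames - 1) * hop + len(win)
    y = np.zeros(total)
    norm = np.zeros(total)
    win_sq = win * win
    step = len(win) // hop
    for k in range(step):
        cls = frames[k::step]
        span = slice(k * hop, k * hop + cls.size)
        y[span] += cls.ravel()
        norm[span] += np.tile(win_sq, len(cls))
    # clamp the envelope: interior samples (norm >= 0.5 for Hann at 50%
    # overlap) divide exactly; the half-window edges, where the true
    # envelope vanishes, are attenuated instead of amplified
    y /= np.maximum(norm, 0.25)
    out = np.zeros(n)
    out[:min(n, total)] = y[:min(n, total)]
    return out


def reduce_noise(
    recording: AudioRecording,
    noise_profile_s: float = 0.5,
    n_std: float = 1.5,
    mask_smooth_bins: tuple[int, int] = (3, 5),
    n_fft: int = 1024,
    hop: int = 512,
) -> AudioRecording:
    """Stationary spectral gating against the leading noise-only head."""
    x = np.asarray(recording.samples, float)
    if recording.duration <= noise_profile_s:
        raise ValueError("recording must be longer than the noise profile")
    if len(x) < n_fft:
        raise ValueError("recording shorter than one STFT frame")

    win = signal.get_window("hann", n_fft, fftbins=True)
    S = _stft(x, win, hop)
    mag = np.abs(S)

    # frames fully inside the noise head: frame k covers
    # [k*hop, k*hop + n_fft)
    n_noise = int(noise_profile_s * recording.sample_rate)
    n_profile = max(0, (n_noise - n_fft) // hop + 1)
    if n_profile < 2:
        raise ValueError("noise head too short for the chosen STFT hop")
    prof_db = 20.0 * np.log10(mag[:, :n_profile] + _EPS)
    thresh_db = prof_db.mean(axis=1) + n_std * prof_db.std(axis=1)
    thresh_lin = 10.0 ** (thresh_db / 20.0)

    mask = (mag > thresh_lin[:, None]).astype(np.float32)
    mask = ndimage.uniform_filter(mask, size=mask_smooth_bins,
                                  mode="nearest")
    np.clip(mask, 0.0, 1.0, out=mask)

    y = _istft(S * mask, win, hop, len(x))
    return AudioRecording(recording.participant_id, recording.group,
                          recording.task, recording.sample_rate, y)


def detect_voice(
    recording: AudioRecording,
    frame_ms: float = 30.0,
    hop_ms: float = 10.0,
    rel_threshold_db: float = 10.0,
    abs_threshold_db: float = -35.0,
    min_speech_ms: float = 100.0,
    max_gap_ms: float = 200.0,
) -> SpeechIntervals:
    """Energy VAD: frame RMS against a percentile noise floor.

    A frame is speech when its RMS (dB) exceeds the 5th-percentile frame
    level by ``rel_threshold_db`` *or* exceeds ``abs_threshold_db``
    outright (signals with no quiet floor, e.g. continuous tones, would
    otherwise yield no speech at all).  Degenerate input yields an empty
    interval list rather than an error.
    """
    x = np.asarray(recording.samples, float)
    sr = recording.sample_rate
    frame = max(1, int(round(frame_ms / 1000.0 * sr)))
    hop = max(1, int(round(hop_ms / 1000.0 * sr)))
    if len(x) < frame:
        return SpeechIntervals([])

    frames = sliding_window_view(x, frame)[::hop]
    rms_db = 10.0 * np.log10(np.mean(frames * frames, axis=1) + _EPS)
    floor = np.percentile(rms_db, 5.0)
    speech = (rms_db > floor + rel_threshold_db) | (rms_db > abs_threshold_db)
    if not speech.any():
        return SpeechIntervals([])

    # runs of speech frames -> (start_frame, end_frame) half-open
    edges = np.flatnonzero(np.diff(np.r_[0, speech.view(np.int8), 0]))
    runs = list(zip(edges[::2], edges[1::2]))

    max_gap_frames = max_gap_ms / 1000.0 * sr / hop
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= max_gap_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    min_frames = min_speech_ms / 1000.0 * sr / hop
    intervals = []
    duration = len(x) / sr
    for s, e in merged:
        if e - s < min_frames:
            continue
        start_s = s * hop / sr
        end_s = min(duration, ((e - 1) * hop + frame) / sr)
        intervals.append((start_s, end_s))
    return SpeechIntervals(intervals)


def trim_to_speech(recording: AudioRecording,
                   intervals: SpeechIntervals) -> AudioRecording:
    """Concatenate the speech spans in order (empty spans -> empty audio)."""
    sr = recording.sample_rate
    n = len(recording.samples)
    pieces = []
    for s, e in intervals.intervals:
        i0, i1 = int(round(s * sr)), min(n, int(round(e * sr)))
        if i1 > n or i0 < 0:
            raise ValueError("interval outside the recording")
        pieces.append(recording.samples[i0:i1])
    samples = (np.concatenate(pieces) if pieces
               else np.empty(0, dtype=float))
    return AudioRecording(recording.participant_id, recording.group,
                          recording.task, sr, samples)


def preprocess_recording(
    recording: AudioRecording,
    noise_profile_s: float = 0.5,
    min_total_speech_s: float = 2.0,
    **vad_kwargs,
) -> tuple[AudioRecording, dict]:
    """Full cleanup chain: gate noise, detect speech, trim.

    Returns the trimmed recording plus a log record with the input and
    retained speech durations and a ``dropped`` flag for recordings whose
    speech content falls below ``min_total_speech_s``.
    """
    denoised = reduce_noise(recording, noise_profile_s=noise_profile_s)
    intervals = detect_voice(denoised, **vad_kwargs)
    trimmed = trim_to_speech(denoised, intervals)
    log = {
        "participant_id": recording.participant_id,
        "task": recording.task,
        "input_duration_s": recording.duration,
        "speech_duration_s": intervals.total_speech_s,
        "dropped": intervals.total_speech_s < min_total_speech_s,
    }
    return trimmed, log
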