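"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (explicit loops, closed
forms) and deliberately avoids the package's own vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np


def autocorr_pitch_hz(x: np.ndarray, sample_rate: int,
                      fmin: float = 60.0, fmax: float = 400.0) -> float:
    """Fundamental frequency via the autocorrelation peak.

    Searches lags corresponding to [fmin, fmax] and refines the peak by
    parabolic interpolation.
    """
    x = np.asarray(x, float) - np.mean(x)
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    lo = int(sample_rate / fmax)
    hi = int(sample_rate / fmin)
    lag = lo + int(np.argmax(ac[lo:hi]))
    if 0 < lag < len(ac) - 1:
        a, b, c = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = a - 2 * b + c
        if denom != 0:
            lag = lag + 0.5 * (a - c) / denom
    return sample_rate / lag


def band_power(x: np.ndarray, sample_rate: int,
               f_lo: float, f_hi: float) -> float:
    """Mean power of the spectrum inside [f_lo, f_hi] via a plain rFFT."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / sample_rate)
    sel = (freqs >= f_lo) & (freqs < f_hi)
    return float(spec[sel].mean())


def mel_breakpoints_hz(fmin: float, fmax: float, n_mels: int) -> np.ndarray:
    """Closed-form mel-scale breakpoints (n_mels + 2 edge/center points)."""
    def mel(f):
        return 2595.0 * math.log10(1.0 + f / 700.0)

    def inv(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    ms = np.linspace(mel(fmin), mel(fmax), n_mels + 2)
    return np.array([inv(m) for m in ms])


def brute_mel_filterbank(sample_rate: int, n_fft: int, n_mels: int
                         ) -> np.ndarray:
    """Triangle filters built with explicit per-bin loops."""
    pts = mel_breakpoints_hz(0.0, sample_rate / 2.0, n_mels)
    n_bins = n_fft // 2 + 1
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, mid, hi = pts[m], pts[m + 1], pts[m + 2]
        for k in range(n_bins):
            f = k * sample_rate / n_fft
            if lo < f <= mid:
                fb[m, k] = (f - lo) / (mid - lo)
            elif mid < f < hi:
                fb[m, k] = (hi - f) / (hi - mid)
            elif f == lo and f == mid:
                fb[m, k] = 1.0
    return fb


def brute_mfcc(samples: np.ndarray, sample_rate: int,
               frame_ms: float = 25.0, n_filters: int = 26,
               n_coeffs: int = 12) -> np.ndarray:
    """MFCC matrix with explicit framing, Hamming, triangles, and DCT."""
    frame = int(round(frame_ms / 1000.0 * sample_rate))
    hop = frame // 2 if frame % 2 == 0 else max(1, int(round(frame * 0.5)))
    n_fft = 1
    while n_fft < frame:
        n_fft *= 2
    window = np.array([0.54 - 0.46 * math.cos(2 * math.pi * n / (frame - 1))
                       for n in range(frame)])
    fb = brute_mel_filterbank(sample_rate, n_fft, n_filters)
    n_frames = (len(samples) - frame) // hop + 1
    out = np.zeros((n_frames, n_coeffs))
    for t in range(n_frames):
        seg = samples[t * hop: t * hop + frame] * window
        spec = np.abs(np.fft.rfft(seg, n=n_fft)) ** 2
        energies = np.array([float(np.dot(fb[m], spec))
                             for m in range(n_filters)])
        logs = np.log(np.maximum(energies, 1e-10))
        for c in range(1, n_coeffs + 1):
            total = 0.0
            for m in range(n_filters):
                total += logs[m] * math.cos(
                    math.pi * c * (2 * m + 1) / (2 * n_filters))
            out[t, c - 1] = total * math.sqrt(2.0 / n_filters)
    return out


def cnn_parameter_count(input_shape=(64, 200),
                        conv_channels=(16, 32, 64, 32),
                        kernel=3, pool_stride=(2, 2),
                        pool_window=(2, 2),
                        dense_units=(128, 64)) -> int:
    """Layer-by-layer arithmetic for the CNN's parameter total."""
    h, w = input_shape
    c_in = 1
    total = 0
    for c_out in conv_channels:
        total += kernel * kernel * c_in * c_out + c_out
        h = (h - pool_window[0]) // pool_stride[0] + 1
        w = (w - pool_window[1]) // pool_stride[1] + 1
        c_in = c_out
    d_in = h * w * c_in
    for d_out in dense_units:
        total += d_in * d_out + d_out
        d_in = d_out
    total += d_in * 1 + 1
    return total


def stft_frame_count(n_samples: int, n_fft: int, hop: int) -> int:
    return 1 + (n_samples - n_fft) // hop


def brute_segment_count(n_frames: int, seg: int, hop: int,
                        pad_if_half: bool = True) -> int:
    """Window placement by explicit enumeration of hop-grid starts."""
    count = 0
    covered = 0
    last_full_start = None
    s = 0
    while s + seg <= n_frames:
        count += 1
        last_full_start = s
        covered = s + seg
        s += hop
    if pad_if_half:
        nxt = last_full_start + hop if last_full_start is not None else 0
        avail = n_frames - nxt
        if avail >= seg / 2 and n_frames > covered:
            count += 1
    return count


def mann_whitney_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic / (n1 * n0), ties = 1/2."""
    pos = scores[np.asarray(y_true) == 1]
    neg = scores[np.asarray(y_true) == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
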