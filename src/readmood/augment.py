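"""SpecAugment-style masking for log-Mel segments.

Training sets are expanded fourfold: each raw segment is joined by a
time-masked, a frequency-masked, and a jointly masked copy.  A frequency
mask blanks ``f`` consecutive mel bands with ``f ~ Uniform{0..F}`` starting
at ``f0 ~ Uniform{0..v-f}``; a time mask blanks ``t ~ Uniform{0..W}``
consecutive frames starting at ``t0 ~ Uniform{0..T-t}``.  Masked cells are
set to the dB floor of the max-referenced spectrogram; everything else —
shape, metadata, label — is untouched.  Augmentation is meant for training
partitions only; the evaluation harness passes validation and test
segments through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectro import DB_FLOOR, LogMelSegment

__all__ = ["AugmentConfig", "freq_mask", "time_mask", "specaugment_expand"]


@dataclass(frozen=True)
class AugmentConfig:
    F: int = 8            # max frequency-mask width, in mel bands
    W: int = 20           # max time-mask width, in frames
    fill: float = DB_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F < 0 or self.W < 0:
            raise ValueError("mask widths must be non-negative")


def freq_mask(segment: LogMelSegment, F: int,
              rng: np.random.Generator,
              fill: float = DB_FLOOR) -> LogMelSegment:
    """Blank one contiguous band of mel channels (width drawn in 0..F)."""
    v = segment.values.shape[0]
    if F > v:
        raise ValueError("F exceeds the number of mel bands")
    f = int(rng.integers(0, F + 1))
    f0 = int(rng.integers(0, v - f + 1))
    values = segment.values.copy()
    values[f0:f0 + f, :] = fill
    return replace(segment, values=values)


def time_mask(segment: LogMelSegment, W: int,
              rng: np.random.Generator,
              fill: float = DB_FLOOR) -> LogMelSegment:
    """Blank one contiguous run of time frames (width drawn in 0..W)."""
    T = segment.values.shape[1]
    if W > T:
        raise ValueError("W exceeds the number of time frames")
    t = int(rng.integers(0, W + 1))
    t0 = int(rng.integers(0, T - t + 1))
    values = segment.values.copy()
    values[:, t0:t0 + t] = fill
    return replace(segment, values=values)


def specaugment_expand(segments: list[LogMelSegment],
                       config: AugmentConfig = AugmentConfig()
                       ) -> list[LogMelSegment]:
    """Raw + time-masked + freq-masked + jointly masked copies (4x).

    Masked copies carry an ``augmented`` tag so leakage checks can tell
    them from raw segments.  Draw order per segment: time mask draws
    first, then the frequency mask, then the joint copy's time and
    frequency draws — all from one generator seeded with ``config.seed``.
    """
    if not segments:
        return []
    shape = segments[0].values.shape
    for s in segments:
        if s.values.shape != shape:
            raise ValueError("segments must share one shape")
    rng = np.random.default_rng(config.seed)
    out: list[LogMelSegment] = []
    for s in segments:
        tm = replace(time_mask(s, config.W, rng, config.fill),
                     augmented="time")
        fm = replace(freq_mask(s, config.F, rng, config.fill),
                     augmented="freq")
        both = replace(
            freq_mask(time_mask(s, config.W, rng, config.fill),
                      config.F, rng, config.fill),
            augmented="time+freq")
        out.extend([s, tm, fm, both])
    return out
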