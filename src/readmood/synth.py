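"""Seeded synthetic read-speech cohorts.

The clinical recordings this pipeline targets (smartphone read speech from
depressed and control speakers) are private, so this module generates a
stand-in cohort with the acoustic structure the analysis relies on:

* mono 44.1 kHz utterances with a leading noise-only head (for the
  stationary noise-gate profile) and interspersed silent pauses (for the
  voice-activity detector);
* task durations drawn per participant around configurable means
  (vowel / digit / passage reading tasks);
* a class contrast in *prosodic and spectral variability*: control-like
  voices carry larger pitch and formant wander, depressed-like voices are
  comparatively monotonous.  The size of the contrast is a single scalar,
  ``variability_gap``; at 0 the two classes are generatively identical.

Speech is produced by a small source-filter model: a sawtooth glottal
source whose fundamental follows a slowly mean-reverting random walk,
filtered by drifting formant resonators, amplitude-modulated at a syllabic
rate, gated by pauses, and mixed with a stationary broadband noise floor.
The point is not linguistic realism but controllable, closed-form-checkable
spectral dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "ClassParams",
    "TaskSpec",
    "CohortConfig",
    "AudioRecording",
    "synthesize_utterance",
    "generate_cohort",
    "save_cohort",
    "load_manifest",
    "load_recording",
    "DEFAULT_TASKS",
]

MDD, HC = "MDD", "HC"

#: per-unit-gap increase of the control group's wander parameters
F0_WANDER_STEP_HZ = 3.0
FORMANT_WANDER_STEP_HZ = 30.0


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its preconditions."""


@dataclass(frozen=True)
class ClassParams:
    """Source-filter parameters for one diagnostic class."""

    f0_mean: float = 140.0          # Hz, mean fundamental
    f0_wander_sd: float = 2.0       # Hz, stationary SD of the f0 random walk
    formant_wander_sd: float = 15.0  # Hz, stationary SD of formant drift
    amplitude_mod_depth: float = 0.15  # depth of the slow amplitude modulation


@dataclass(frozen=True)
class TaskSpec:
    """One reading task: name plus per-participant duration distribution."""

    name: str
    mean_duration_s: float
    sd_duration_s: float


# Task duration defaults sit midway between the two groups' reported
# per-task means (and SDs) for vowel / digit / passage reading.
DEFAULT_TASKS: dict[str, TaskSpec] = {
    "vowel": TaskSpec("vowel", 14.0, 4.1),
    "digit": TaskSpec("digit", 15.0, 4.9),
    "passage": TaskSpec("passage", 80.0, 12.7),
}


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``variability_gap`` scales the control-minus-depressed difference in
    ``f0_wander_sd`` and ``formant_wander_sd``; 0 means the classes share
    identical generative parameters (a null cohort).
    """

    n_participants: int = 20
    mdd_fraction: float = 0.5
    tasks: dict[str, TaskSpec] = field(
        default_factory=lambda: dict(DEFAULT_TASKS))
    sample_rate: int = 44100
    noise_head_s: float = 0.6
    pause_rate: float = 2.0          # pauses per 10 s of speech
    base_params: ClassParams = field(default_factory=ClassParams)
    variability_gap: float = 1.0
    noise_floor_db: float = -60.0    # dBFS RMS of the stationary background
    seed: int = 0

    def class_params(self) -> dict[str, ClassParams]:
        """Per-class parameters; the gap widens only the HC wander terms."""
        base = self.base_params
        hc = ClassParams(
            f0_mean=base.f0_mean,
            f0_wander_sd=base.f0_wander_sd
            + self.variability_gap * F0_WANDER_STEP_HZ,
            formant_wander_sd=base.formant_wander_sd
            + self.variability_gap * FORMANT_WANDER_STEP_HZ,
            amplitude_mod_depth=base.amplitude_mod_depth,
        )
        return {MDD: base, HC: hc}

    def validate(self) -> None:
        if self.n_participants < 2:
            raise InvalidConfigError("need at least 2 participants")
        if not (0.0 <= self.mdd_fraction <= 1.0):
            raise InvalidConfigError("mdd_fraction must lie in [0, 1]")
        n_mdd = int(round(self.mdd_fraction * self.n_participants))
        if n_mdd == 0 or n_mdd == self.n_participants:
            raise InvalidConfigError("both classes must be non-empty")
        if not self.tasks:
            raise InvalidConfigError("at least one task is required")
        if self.sample_rate <= 0:
            raise InvalidConfigError("sample_rate must be positive")
        if self.variability_gap < 0:
            raise InvalidConfigError("variability_gap must be >= 0")
        for t in self.tasks.values():
            if t.mean_duration_s <= self.noise_head_s:
                raise InvalidConfigError(
                    f"task {t.name!r}: duration must exceed the noise head")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = {k: asdict(v) for k, v in self.tasks.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "tasks" in d:
            d["tasks"] = {k: TaskSpec(**v) if isinstance(v, dict) else v
                          for k, v in d["tasks"].items()}
        if isinstance(d.get("base_params"), dict):
            d["base_params"] = ClassParams(**d["base_params"])
        return cls(**d)


@dataclass
class AudioRecording:
    """One participant-task waveform with its label and sampling metadata."""

    participant_id: str
    group: str                      # "MDD" or "HC"
    task: str
    sample_rate: int
    samples: np.ndarray             # mono float array in [-1, 1]

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def label(self) -> int:
        """Binary label, positive class = MDD."""
        return 1 if self.group == MDD else 0


def _ar1_track(rng: np.random.Generator, n: int, mean: float,
               stat_sd: float, rho: float = 0.99) -> np.ndarray:
    """Mean-reverting AR(1) walk whose stationary SD equals ``stat_sd``."""
    if stat_sd == 0.0:
        return np.full(n, mean)
    step_sd = stat_sd * np.sqrt(1.0 - rho * rho)
    steps = rng.normal(0.0, step_sd, size=n)
    x = np.empty(n)
    acc = rng.normal(0.0, stat_sd)
    for i in range(n):
        acc = rho * acc + steps[i]
        x[i] = acc
    return mean + x


# formant resonator layout: center frequencies and bandwidths in Hz
_FORMANT_CENTERS = (500.0, 1500.0, 2500.0)
_FORMANT_BWS = (80.0, 120.0, 180.0)

_BLOCK_S = 0.1  # resonator centers and f0 are updated on this grid


def synthesize_utterance(
    participant_seed,
    class_params: ClassParams,
    duration_s: float,
    sample_rate: int = 44100,
    *,
    noise_head_s: float = 0.6,
    pause_rate: float = 2.0,
    noise_floor_db: float = -60.0,
) -> np.ndarray:
    """Render one utterance waveform.

    ``participant_seed`` may be an integer or a ``numpy`` ``SeedSequence`` /
    ``Generator``; the same seed always yields bit-identical samples.
    Returns a float64 array with peak speech amplitude 0.9 plus the
    stationary background noise, clipped to [-1, 1].
    """
    if duration_s <= 0 or sample_rate <= 0:
        raise InvalidConfigError("duration and sample_rate must be positive")
    if not (60.0 < class_params.f0_mean < 400.0):
        raise InvalidConfigError("f0_mean must lie in (60, 400) Hz")
    if duration_s <= noise_head_s:
        raise InvalidConfigError("duration must exceed the noise head")

    rng = (participant_seed if isinstance(participant_seed, np.random.Generator)
           else np.random.default_rng(participant_seed))

    n_total = int(round(duration_s * sample_rate))
    n_head = int(round(noise_head_s * sample_rate))
    n_speech = n_total - n_head
    block = max(1, int(round(_BLOCK_S * sample_rate)))
    n_blocks = int(np.ceil(n_speech / block))

    # --- harmonic source with wandering fundamental ---------------------
    f0_blocks = _ar1_track(rng, n_blocks, class_params.f0_mean,
                           class_params.f0_wander_sd)
    np.clip(f0_blocks, 0.5 * class_params.f0_mean,
            1.9 * class_params.f0_mean, out=f0_blocks)
    t_blocks = (np.arange(n_blocks) + 0.5) * block
    f0 = np.interp(np.arange(n_speech), t_blocks, f0_blocks)
    cycles = np.cumsum(f0) / sample_rate
    source = 2.0 * (cycles % 1.0) - 1.0      # sawtooth, -1 rising to 1

    # --- drifting formant resonators (block-stationary filtering) -------
    centers = np.empty((len(_FORMANT_CENTERS), n_blocks))
    for j, c in enumerate(_FORMANT_CENTERS):
        track = _ar1_track(rng, n_blocks, c, class_params.formant_wander_sd)
        centers[j] = np.clip(track, 0.4 * c,
                             min(1.8 * c, 0.45 * sample_rate))
    voiced = np.empty(n_speech)
    zi = [signal.sosfilt_zi(np.atleast_2d(
        np.hstack(signal.iirpeak(c / (sample_rate / 2), Q=c / b)))) * 0.0
        for c, b in zip(_FORMANT_CENTERS, _FORMANT_BWS)]
    for ib in range(n_blocks):
        lo, hi = ib * block, min((ib + 1) * block, n_speech)
        seg = source[lo:hi]
        for j, bw in enumerate(_FORMANT_BWS):
            b, a = signal.iirpeak(centers[j, ib] / (sample_rate / 2),
                                  Q=centers[j, ib] / bw)
            sos = np.atleast_2d(np.hstack([b, a]))
            seg, zi[j] = signal.sosfilt(sos, seg, zi=zi[j])
        voiced[lo:hi] = seg

    # --- amplitude structure: slow modulation + syllabic rhythm ---------
    t = np.arange(n_speech) / sample_rate
    slow_rate = rng.uniform(1.5, 3.5)
    slow = 1.0 + class_params.amplitude_mod_depth * np.sin(
        2.0 * np.pi * slow_rate * t + rng.uniform(0, 2 * np.pi))
    syllabic = 0.7 + 0.3 * np.cos(
        2.0 * np.pi * 4.0 * t + rng.uniform(0, 2 * np.pi))
    voiced *= slow * syllabic

    # --- pauses: cosine-gated silent spans ------------------------------
    gate = np.ones(n_speech)
    speech_s = n_speech / sample_rate
    if pause_rate > 0 and speech_s > 3.0:
        n_pauses = max(1, int(rng.poisson(pause_rate * speech_s / 10.0)))
        ramp_n = int(0.02 * sample_rate)
        ramp = 0.5 * (1 + np.cos(np.linspace(0, np.pi, ramp_n)))
        for _ in range(n_pauses):
            p_dur = rng.uniform(0.3, 0.7)
            p_n = int(p_dur * sample_rate)
            margin = int(0.5 * sample_rate)
            if n_speech - p_n - 2 * (margin + ramp_n) <= 0:
                continue
            start = int(rng.integers(margin + ramp_n,
                                     n_speech - p_n - margin - ramp_n))
            gate[start - ramp_n:start] = np.minimum(
                gate[start - ramp_n:start], ramp)
            gate[start:start + p_n] = 0.0
            gate[start + p_n:start + p_n + ramp_n] = np.minimum(
                gate[start + p_n:start + p_n + ramp_n], ramp[::-1])
    voiced *= gate

    peak = np.max(np.abs(voiced))
    if peak > 0:
        voiced *= 0.9 / peak

    out = np.zeros(n_total)
    out[n_head:] = voiced
    noise_rms = 10.0 ** (noise_floor_db / 20.0)
    out += rng.normal(0.0, noise_rms, size=n_total)
    return np.clip(out, -1.0, 1.0)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[AudioRecording], pd.DataFrame]:
    """Generate one recording per participant per configured task.

    Returns the recordings plus a manifest table with columns
    ``participant_id, group, task, duration_s, path`` (path empty for
    in-memory cohorts).  Identical config and seed give bit-identical
    output; per-participant random streams are derived by fixed spawning
    of ``(root seed, participant index, task index)``.
    """
    config.validate()
    n_mdd = int(round(config.mdd_fraction * config.n_participants))
    params = config.class_params()
    task_list = sorted(config.tasks)

    recordings: list[AudioRecording] = []
    rows = []
    for i in range(config.n_participants):
        pid = f"P{i:03d}"
        group = MDD if i < n_mdd else HC
        for ti, tname in enumerate(task_list):
            spec = config.tasks[tname]
            ss = np.random.SeedSequence(config.seed, spawn_key=(i, ti))
            rng = np.random.default_rng(ss)
            lo = max(config.noise_head_s + 2.5,
                     spec.mean_duration_s - 2.5 * spec.sd_duration_s)
            hi = spec.mean_duration_s + 2.5 * spec.sd_duration_s
            duration = float(np.clip(
                rng.normal(spec.mean_duration_s, spec.sd_duration_s), lo, hi))
            samples = synthesize_utterance(
                rng, params[group], duration, config.sample_rate,
                noise_head_s=config.noise_head_s,
                pause_rate=config.pause_rate,
                noise_floor_db=config.noise_floor_db)
            rec = AudioRecording(pid, group, tname,
                                 config.sample_rate, samples)
            recordings.append(rec)
            rows.append({"participant_id": pid, "group": group,
                         "task": tname, "duration_s": rec.duration,
                         "path": ""})
    manifest = pd.DataFrame(rows)
    return recordings, manifest


def save_cohort(recordings: list[AudioRecording], manifest: pd.DataFrame,
                outdir: str | Path,
                config: CohortConfig | None = None) -> pd.DataFrame:
    """Write WAVs (32-bit float RIFF), manifest CSV + JSONL, config YAML.

    Returns a manifest copy whose ``path`` column points at the files.
    """
    outdir = Path(outdir)
    wav_dir = outdir / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for rec in recordings:
        name = f"{rec.participant_id}_{rec.task}.wav"
        wavfile.write(wav_dir / name, rec.sample_rate,
                      rec.samples.astype(np.float32))
        sel = ((manifest.participant_id == rec.participant_id)
               & (manifest.task == rec.task))
        manifest.loc[sel, "path"] = str(Path("wav") / name)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "manifest.jsonl", "w") as fh:
        for row in manifest.to_dict(orient="records"):
            fh.write(json.dumps(row) + "\n")
    if config is not None:
        with open(outdir / "cohort_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "group", "task", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return manifest


def load_recording(row, base_dir: str | Path = ".") -> AudioRecording:
    """Read one manifest row's WAV file into an :class:`AudioRecording`."""
    sr, samples = wavfile.read(Path(base_dir) / row["path"])
    if samples.ndim != 1:
        raise ValueError("expected mono audio")
    if samples.dtype.kind == "i":
        samples = samples / float(np.iinfo(samples.dtype).max)
    return AudioRecording(str(row["participant_id"]), row["group"],
                          row["task"], sr, np.asarray(samples, float))
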