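import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from readmood.synth import (AudioRecording, CohortConfig, TaskSpec,
                            generate_cohort)

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_tone(freq: float, duration_s: float, sample_rate: int = 44100,
              amplitude: float = 0.5) -> np.ndarray:
    t = np.arange(int(duration_s * sample_rate)) / sample_rate
    return amplitude * np.sin(2 * np.pi * freq * t)


def as_recording(samples, sample_rate: int = 44100, group: str = "HC",
                 pid: str = "P000", task: str = "test") -> AudioRecording:
    return AudioRecording(pid, group, task, sample_rate,
                          np.asarray(samples, float))


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants, one short vowel-like task, strong class contrast."""
    cfg = CohortConfig(
        n_participants=12,
        tasks={"vowel": TaskSpec("vowel", 5.0, 0.5)},
        variability_gap=2.0,
        seed=3,
    )
    recordings, manifest = generate_cohort(cfg)
    return cfg, recordings, manifest
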