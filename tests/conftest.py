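"""Shared fixtures: synthetic cohorts analyzed once per test session."""

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from rippletherm.core import DetectionParams
from rippletherm.pipeline import SessionResult, analyze_recording
from rippletherm.synth import (
    GroundTruth,
    ds_preset,
    simulate_baseline,
    simulate_session,
    wt_preset,
)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@dataclass
class SessionBundle:
    recording: object
    truth: GroundTruth
    result: SessionResult


@pytest.fixture(scope="session")
def params():
    return DetectionParams()


@pytest.fixture(scope="session")
def ds_cohort():
    """Six DS thermal-induction sessions, analyzed."""
    preset = ds_preset()
    out = []
    for i in range(6):
        rec, truth = simulate_session(preset, 100 + i)
        out.append(SessionBundle(rec, truth, analyze_recording(rec)))
    return out


@pytest.fixture(scope="session")
def wt_trio():
    """Three WT thermal-induction sessions, analyzed."""
    preset = wt_preset()
    out = []
    for i in range(3):
        rec, truth = simulate_session(preset, 200 + i)
        out.append(SessionBundle(rec, truth, analyze_recording(rec)))
    return out


@pytest.fixture(scope="session")
def wt_baseline():
    """900 s constant-36-degC WT recording, analyzed (>=200 SPW-R)."""
    rec, truth = simulate_baseline(wt_preset(), 900.0, 11)
    return SessionBundle(rec, truth, analyze_recording(rec))


@pytest.fixture(scope="session")
def ds_baseline():
    rec, truth = simulate_baseline(ds_preset(), 900.0, 11)
    return SessionBundle(rec, truth, analyze_recording(rec))


def truth_outside_gtc_guard(bundle: SessionBundle, kind: str,
                            guard: float = 2.0) -> np.ndarray:
    """Injected event times of one type, excluding the GTC guard window."""
    times = bundle.truth.times_of(kind)
    span = bundle.result.gtc_span
    if span is None:
        return times
    return times[(times < span[0] - guard) | (times > span[1] + guard)]
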