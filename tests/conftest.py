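"""Shared fixtures: synthetic records are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ecgmedian import SynthConfig, synth_record
from ecgmedian.pipeline import analyze_record


@pytest.fixture(scope="session")
def sinus_record():
    """One clean minute of 75 bpm sinus rhythm at 250 Hz."""
    return synth_record(SynthConfig(fs=250, duration=60, rhythm="sinus", seed=11))


@pytest.fixture(scope="session")
def bigeminy_record():
    return synth_record(SynthConfig(fs=250, duration=60, rhythm="bigeminy", seed=11))


@pytest.fixture(scope="session")
def svt_constant_record():
    """Strictly deterministic SVT minute: constant 0.32 s RR, no noise."""
    return synth_record(SynthConfig(fs=250, duration=60, rhythm="svt", seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def af_record():
    return synth_record(SynthConfig(fs=250, duration=60, rhythm="af", seed=11))


@pytest.fixture(scope="session")
def analyzed_sinus(sinus_record):
    return analyze_record(sinus_record.record)


def beat_sensitivity(annotated, detected_indices, tolerance_s=0.150):
    """Fraction of ground-truth beats matched by a detection."""
    det = np.asarray(detected_indices)
    tol = tolerance_s * annotated.record.fs
    hits = sum(bool(np.any(np.abs(det - t) <= tol)) for t in annotated.truth_samples)
    return hits / len(annotated.truth_samples)
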