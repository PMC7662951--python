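"""Sampling-rate-derived sliding-window structure.

The stream is segmented into windows built from ``n_particles`` "particle
times" of ``particle_s`` seconds each.  Consecutive windows overlap by
exactly one particle time, so

    window = particle_s * n_particles
    step   = particle_s * (n_particles - 1)
    overlap = particle_s

With the defaults (4 s particles, 3 per window) a one-minute stream is
covered by seven 12 s windows stepping by 8 s; an alternative 6 s / 4
structure gives three 24 s windows.  Both per-minute structures satisfy
the relations above, which are therefore adopted as the defining rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .records import EcgRecord

#: Trailing remnants shorter than this (s) are dropped: too short to hold
#: a full QRS context.
MIN_PARTIAL_WINDOW_S = 2.0


@dataclass(frozen=True)
class WindowPlan:
    """Derived segmentation constants for one sampling rate."""

    fs: float
    particle_s: float
    n_particles: int
    window_s: float
    step_s: float
    overlap_s: float
    windows_per_minute: float
    window_n: int
    step_n: int

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.fs,
            "particle_time_s": self.particle_s,
            "n_particle_times": self.n_particles,
        }


@dataclass
class SlidingWindow:
    """One window of the stream: index, first-sample offset, amplitudes."""

    n: int
    start: int
    samples: np.ndarray

    @property
    def stop(self) -> int:
        return self.start + self.samples.size


def derive_window_plan(fs: float, particle_s: float = 4.0, n_particles: int = 3) -> WindowPlan:
    """Derive the sliding-window structure for a sampling rate.

    Parameters
    ----------
    fs : float
        Sampling rate in samples/s (>= 50).
    particle_s : float
        Particle-time length in seconds.
    n_particles : int
        Particle times per window (>= 2).

    Returns
    -------
    WindowPlan
        Defaults give a 12 s window, 8 s step, 4 s overlap and 7 windows
        per minute at any sampling rate.
    """
    if fs < 50:
        raise ValueError(f"sampling rate must be >= 50 samples/s, got {fs}")
    if particle_s <= 0:
        raise ValueError("particle time must be positive")
    if n_particles < 2:
        raise ValueError("need at least 2 particle times per window")
    window_s = particle_s * n_particles
    step_s = particle_s * (n_particles - 1)
    overlap_s = particle_s
    windows_per_minute = (60.0 - window_s) / step_s + 1.0
    return WindowPlan(
        fs=float(fs),
        particle_s=float(particle_s),
        n_particles=int(n_particles),
        window_s=window_s,
        step_s=step_s,
        overlap_s=overlap_s,
        windows_per_minute=windows_per_minute,
        window_n=int(round(window_s * fs)),
        step_n=int(round(step_s * fs)),
    )


def iterate_windows(record: EcgRecord, plan: WindowPlan) -> Iterator[SlidingWindow]:
    """Iterate a record through the plan's half-open windows.

    Windows start at 0, step_n, 2*step_n, ...; a final partial window is
    emitted if at least ``MIN_PARTIAL_WINDOW_S`` of signal remains beyond
    the last full window.
    """
    if record.fs != plan.fs:
        raise ValueError(f"record sampled at {record.fs} Hz but plan derived for {plan.fs} Hz")
    if record.n_samples < 1:
        raise ValueError("empty record")
    min_partial_n = int(round(MIN_PARTIAL_WINDOW_S * plan.fs))
    n = 0
    start = 0
    length = record.n_samples
    while start < length:
        remaining = length - start
        if remaining < plan.window_n:
            # partial tail: only if long enough and not already fully covered
            if start > 0 and remaining < min_partial_n:
                break
        yield SlidingWindow(n=n, start=start, samples=record.samples[start:start + plan.window_n])
        if start + plan.window_n >= length:
            break
        n += 1
        start += plan.step_n
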