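"""R-peak detection from the adaptive-median difference signal.

Candidate QRS intervals are the runs where a running-maximum envelope of
the difference signal D reaches an adaptive threshold — the average of
the top 50% of the envelope.  One peak is taken per run at the argmax of
D, classified as a normal (positive) R if the original amplitude exceeds
the window mean and as abnormal (negative R / PVC) otherwise, and
detections from overlapping windows are merged with a physiological
refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .median import FilteredWindow, adaptive_median_filter
from .records import EcgRecord
from .windows import SlidingWindow, WindowPlan, derive_window_plan, iterate_windows

#: Minimum separation of accepted peaks (s) — the physiological lower
#: bound on the RR interval.
REFRACTORY_S = 0.200

#: Half-width (s) of the snap-to-extremum search around the argmax of D.
SNAP_S = 0.025

NORMAL = "normal_positive"
ABNORMAL = "abnormal"


@dataclass
class RPeak:
    """A detected R peak: sample index, time, original-signal amplitude,
    polarity class, and the difference-signal value backing it."""

    index: int
    time: float
    amplitude: float
    polarity: str
    d_value: float = 0.0


def max_filter(D: np.ndarray, fs: float) -> np.ndarray:
    """Running maximum of D over a centered window of round(F/8) samples."""
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        raise ValueError("empty input")
    size = max(1, round(fs / 8.0))
    return ndimage.maximum_filter1d(D, size=size, mode="nearest")


def adaptive_threshold(envelope: np.ndarray) -> float:
    """Average of the top 50% (by value) of the envelope samples."""
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        raise ValueError("empty envelope")
    k = -(-env.size // 2)  # ceil(n/2)
    top = np.sort(env)[-k:]
    return float(top.mean())


def detect_r_in_window(
    window: SlidingWindow,
    fw: FilteredWindow,
    fs: float,
    refractory_s: float = REFRACTORY_S,
) -> list[RPeak]:
    """Detect R peaks inside one sliding window.

    Returns peaks with absolute sample indices.  An all-flat window
    (zero threshold) yields no peaks.
    """
    S = np.asarray(window.samples, dtype=float)
    env = max_filter(fw.D, fs)
    thr = adaptive_threshold(env)
    if thr <= 0:
        return []
    above = env >= thr
    if not above.any():
        return []
    # maximal runs of above-threshold envelope
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = np.r_[0 if above[0] else [], edges[~above[edges]] + 1].astype(int)
    stops = np.r_[edges[above[edges]] + 1, [S.size] if above[-1] else []].astype(int)

    mean_s = float(S.mean())
    snap_n = max(1, round(SNAP_S * fs))
    peaks: list[RPeak] = []
    for a, b in zip(starts, stops):
        i = a + int(np.argmax(fw.D[a:b]))
        polarity = NORMAL if S[i] > mean_s else ABNORMAL
        lo, hi = max(0, i - snap_n), min(S.size, i + snap_n + 1)
        j = lo + int(np.argmax(S[lo:hi]) if polarity == NORMAL else np.argmin(S[lo:hi]))
        peaks.append(
            RPeak(
                index=window.start + j,
                time=(window.start + j) / fs,
                amplitude=float(S[j]),
                polarity=polarity,
                d_value=float(fw.D[i]),
            )
        )
    return _enforce_refractory(peaks, int(round(refractory_s * fs)))


def _enforce_refractory(peaks: list[RPeak], refractory_n: int) -> list[RPeak]:
    """Peaks closer than the refractory period keep the larger D value."""
    kept: list[RPeak] = []
    for p in sorted(peaks, key=lambda q: q.index):
        if kept and p.index - kept[-1].index < refractory_n:
            if p.d_value > kept[-1].d_value:
                kept[-1] = p
        else:
            kept.append(p)
    return kept


def merge_window_detections(
    per_window_peaks: list[list[RPeak]],
    plan: WindowPlan,
    refractory_s: float = REFRACTORY_S,
) -> list[RPeak]:
    """Collapse duplicate detections from overlap zones.

    Peaks (absolute indices) within the refractory period of each other
    are duplicates of one beat; the one with the larger D survives.
    Output is strictly increasing in index.
    """
    flat = [p for peaks in per_window_peaks for p in peaks]
    return _enforce_refractory(flat, int(round(refractory_s * plan.fs)))


def detect_r_peaks(
    record: EcgRecord,
    plan: WindowPlan | None = None,
    refractory_s: float = REFRACTORY_S,
) -> list[RPeak]:
    """Full pipeline: window, filter, detect, merge.

    Convenience wrapper running the adaptive median filter and peak
    detection over every sliding window of the record.
    """
    if plan is None:
        plan = derive_window_plan(record.fs)
    per_window = []
    for window in iterate_windows(record, plan):
        try:
            fw = adaptive_median_filter(window, record.fs)
        except ValueError:
            continue  # trailing window too short for the maximal filter
        per_window.append(detect_r_in_window(window, fw, record.fs, refractory_s))
    return merge_window_detections(per_window, plan, refractory_s)
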