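"""Beat delineation: Q onset, S offset, P and T fiducials around each R.

The searches run on a 10 ms moving-average smoothed copy of the signal.
QRS bounds are the nearest points before/after R where the absolute
slope falls below 10% of the peak slope within +/-150 ms; the P peak is
the most prominent interior extremum in a window ending 40 ms before the
Q onset, and the T peak the largest extremum 80-400 ms after the S
offset.  A P wave whose prominence is below 5% of the R amplitude is
reported absent — the behaviour exploited by the merged-P-T test for
supraventricular tachycardia and by the atrial-activity feature for AF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .records import EcgRecord
from .rpeaks import RPeak

SMOOTH_S = 0.010          # moving-average width for all searches
QRS_SEARCH_S = 0.150      # Q-onset / S-offset search span around R
SLOPE_FRACTION = 0.10     # slope threshold as a fraction of the peak slope
P_EARLY_S = 0.300         # P search window: [q_onset - 300 ms, q_onset - 40 ms]
P_LATE_S = 0.040
P_PROMINENCE_FRACTION = 0.05  # of |R| amplitude
P_FLANK_SLOPE_FRACTION = 0.05  # gentler bound for the low-slope P wave
T_EARLY_S = 0.080         # T search window: [s_offset + 80 ms, s_offset + 400 ms]
T_LATE_S = 0.400
CONTEXT_S = 0.5           # context needed on each side for a full delineation


@dataclass
class Beat:
    """One delineated beat.  Fiducials are 0-based sample indices;
    missing ones are None.  ``partial`` flags beats too close to the
    record edge for a full search."""

    r: RPeak
    q_onset: int | None = None
    s_offset: int | None = None
    p_onset: int | None = None
    p_peak: int | None = None
    p_offset: int | None = None
    t_peak: int | None = None
    qrs_width: float | None = None
    label: str = "N"
    partial: bool = False


def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    size = max(1, round(SMOOTH_S * fs))
    return ndimage.uniform_filter1d(np.asarray(x, dtype=float), size=size, mode="nearest")


#: The walk past the QRS ends only where the signal has also returned
#: toward baseline: this carries it across the flat top of a slurred
#: wide complex without letting it run into neighboring waves.
QRS_AMP_FRACTION = 0.20


def _slope_bound(
    smoothed: np.ndarray, slope_abs: np.ndarray, r_idx: int, span: int, direction: int
) -> int:
    """QRS bound on one side of R.

    Starting from the steepest point of the flank (the apex itself has
    near-zero slope and must be skipped), walk outward until the slope
    magnitude drops below ``SLOPE_FRACTION`` of the flank peak *and*
    the amplitude has returned within ``QRS_AMP_FRACTION`` of the R
    excursion over the local baseline.
    """
    n = slope_abs.size
    lo = max(0, r_idx - span)
    hi = min(n, r_idx + span + 1)
    baseline = float(np.median(smoothed[max(0, r_idx - 2 * span):min(n, r_idx + 2 * span)]))
    amp_thr = QRS_AMP_FRACTION * abs(smoothed[r_idx] - baseline)
    if direction < 0:
        seg = slope_abs[lo:r_idx + 1]
        thr = SLOPE_FRACTION * seg.max()
        i = lo + int(np.argmax(seg))
        while i > lo and (slope_abs[i - 1] >= thr or abs(smoothed[i - 1] - baseline) >= amp_thr):
            i -= 1
        return i
    seg = slope_abs[r_idx:hi]
    thr = SLOPE_FRACTION * seg.max()
    i = r_idx + int(np.argmax(seg))
    while i < hi - 1 and (slope_abs[i + 1] >= thr or abs(smoothed[i + 1] - baseline) >= amp_thr):
        i += 1
    return i


def _largest_extremum(seg: np.ndarray, min_prominence: float) -> tuple[int, float] | None:
    """Most prominent interior peak of |seg - baseline|, either sign."""
    best: tuple[int, float] | None = None
    for sign in (1.0, -1.0):
        idx, props = sps.find_peaks(sign * seg, prominence=min_prominence)
        if idx.size:
            k = int(np.argmax(props["prominences"]))
            cand = (int(idx[k]), float(props["prominences"][k]))
            if best is None or cand[1] > best[1]:
                best = cand
    return best


def delineate_beat(
    record: EcgRecord,
    r: RPeak,
    prev_r: RPeak | None = None,
    next_r: RPeak | None = None,
) -> Beat:
    """Delineate one beat around a detected R peak.

    ``prev_r`` bounds the P search so the previous beat's QRS is never
    mistaken for a P wave; ``next_r`` bounds the T search the same way
    at fast rates.  Beats with less than 0.5 s of context on either
    side are returned partial, with the missing fields None.
    """
    fs = record.fs
    n = record.n_samples
    if not 0 <= r.index < n:
        raise ValueError("R peak outside the record")
    smoothed = _smooth(record.samples, fs)
    slope_abs = np.abs(np.gradient(smoothed))
    context_n = round(CONTEXT_S * fs)
    partial = r.index < context_n or r.index > n - 1 - context_n

    beat = Beat(r=r, partial=partial)
    span = round(QRS_SEARCH_S * fs)
    if r.index > 0:
        beat.q_onset = _slope_bound(smoothed, slope_abs, r.index, span, -1)
    if r.index < n - 1:
        beat.s_offset = _slope_bound(smoothed, slope_abs, r.index, span, +1)
    if beat.q_onset is not None and beat.s_offset is not None and beat.s_offset > beat.q_onset:
        beat.qrs_width = (beat.s_offset - beat.q_onset) / fs

    r_amp = abs(record.samples[r.index])
    min_prom = P_PROMINENCE_FRACTION * r_amp

    if beat.q_onset is not None:
        lo = beat.q_onset - round(P_EARLY_S * fs)
        hi = beat.q_onset - round(P_LATE_S * fs)
        if prev_r is not None:
            # stay clear of the previous QRS
            lo = max(lo, prev_r.index + round(0.120 * fs))
        lo = max(lo, 0)
        if hi - lo >= 3:
            found = _largest_extremum(smoothed[lo:hi], min_prom)
            if found is not None:
                beat.p_peak = lo + found[0]
                beat.p_onset, beat.p_offset = _p_flanks(slope_abs, beat.p_peak, lo, hi)

    if beat.s_offset is not None:
        lo = beat.s_offset + round(T_EARLY_S * fs)
        hi = min(beat.s_offset + round(T_LATE_S * fs), n)
        if next_r is not None:
            hi = min(hi, next_r.index - round(0.060 * fs))
        if hi - lo >= 3:
            seg = smoothed[lo:hi]
            found = _largest_extremum(seg, 0.02 * r_amp)
            if found is not None:
                beat.t_peak = lo + found[0]
            else:
                # no interior extremum: the apex sits at the window edge
                # (fast rhythms); take the excursion from the far edge
                beat.t_peak = lo + int(np.argmax(np.abs(seg - seg[-1])))
    return beat


def _p_flanks(slope_abs: np.ndarray, p_peak: int, lo: int, hi: int) -> tuple[int, int]:
    """P onset/offset: walk outward from each flank's steepest point to
    the first samples where the slope magnitude falls below
    ``P_FLANK_SLOPE_FRACTION`` of the P region's peak slope (an argmin
    over the window would land on flat baseline far from the wave)."""
    region = slope_abs[lo:hi]
    thr = P_FLANK_SLOPE_FRACTION * region.max() if region.size else 0.0
    # start each walk at the flank's steepest point, not the (flat) peak
    onset = lo + int(np.argmax(slope_abs[lo:p_peak])) if p_peak > lo else lo
    while onset > lo and slope_abs[onset - 1] >= thr:
        onset -= 1
    offset = p_peak + 1 + int(np.argmax(slope_abs[p_peak + 1:hi])) if hi > p_peak + 1 else hi - 1
    while offset < hi - 1 and slope_abs[offset + 1] >= thr:
        offset += 1
    return onset, offset


def p_wave_area(record: EcgRecord, beat: Beat, amplitude_grid_mv: float = 0.1) -> float:
    """Triangular P-wave area in grid units squared.

    The triangle has vertices at the P onset, peak and offset; the peak
    amplitude is corrected to the onset-offset chord.  Base is measured
    in samples and height in amplitude grid units (one standard ECG
    paper box, 0.1 mV, per unit), matching the scale of the analytic
    maximum area used by the atrial-activity feature.  Absent P -> 0.
    """
    if beat.p_onset is None or beat.p_peak is None or beat.p_offset is None:
        return 0.0
    x = np.array([beat.p_onset, beat.p_peak, beat.p_offset], dtype=float)
    y = record.samples[x.astype(int)]
    base = x[2] - x[0]
    if base <= 0:
        return 0.0
    # peak height above the onset-offset chord
    chord = y[0] + (y[2] - y[0]) * (x[1] - x[0]) / base
    height = abs(y[1] - chord) / amplitude_grid_mv
    return float(base * height / 2.0)
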