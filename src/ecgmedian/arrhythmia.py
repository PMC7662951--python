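"""Rule-based per-minute arrhythmia classification.

Each whole minute of the stream is classified from its detected beats:
rate (bradycardia < 60 bpm, tachycardia > 100 bpm), bigeminy/trigeminy
from the short/middle/long structure of the RR intervals, per-beat PVC
labels (wide QRS or negative R), ventricular tachycardia (a run of >= 3
consecutive PVCs at >= 100 bpm), supraventricular tachycardia (150-250
bpm with merged P-T waves), and an atrial-fibrillation call from the
five-feature severity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiducials import Beat
from .records import EcgRecord

BRADYCARDIA_BPM = 60.0
TACHYCARDIA_BPM = 100.0
VT_MIN_RUN = 3
VT_MIN_BPM = 100.0
SVT_MIN_BPM = 150.0
SVT_MAX_BPM = 250.0
SVT_MERGED_P_FRACTION = 0.70
PVC_QRS_WIDTH_S = 0.120
#: Minimum gap (s) between sorted RR values for a class split.
RR_SPLIT_GAP_S = 0.050


@dataclass
class RRSeries:
    """RR intervals partitioned into short/middle/long classes."""

    intervals: np.ndarray
    labels: np.ndarray  # 'S' / 'M' / 'L' per interval
    t_obs: float        # observation time (s)

    def _cls(self, label: str) -> np.ndarray:
        return self.intervals[self.labels == label]

    @property
    def n_short(self) -> int:
        return int((self.labels == "S").sum())

    @property
    def n_middle(self) -> int:
        return int((self.labels == "M").sum())

    @property
    def n_long(self) -> int:
        return int((self.labels == "L").sum())

    def mean(self, label: str) -> float:
        vals = self._cls(label)
        return float(vals.mean()) if vals.size else float("nan")


@dataclass
class BigeminyParams:
    """Decision constants for the bigeminy/trigeminy rule.

    th_min/th_max bound the average long-short difference; diff_ls and
    diff_ms are count tolerances (None -> max(2, 10% of beats))."""

    th_min: float = 0.10
    th_max: float = 0.60
    diff_ls: int | None = None
    diff_ms: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.th_min < self.th_max:
            raise ValueError("need 0 < th_min < th_max")

    def tolerance(self, n: int, which: str) -> int:
        explicit = self.diff_ls if which == "ls" else self.diff_ms
        return explicit if explicit is not None else max(2, round(0.1 * n))


@dataclass
class ArrhythmiaCall:
    """One rhythm call for one processing unit (minute)."""

    type: str  # bradycardia|tachycardia|bigeminy|trigeminy|PVC|VT|SVT|AF|none
    minute: int = 0
    evidence: dict = field(default_factory=dict)


def classify_rate(bpm: float) -> str:
    """Strict thresholds: < 60 bradycardia, > 100 tachycardia."""
    if bpm <= 0:
        raise ValueError("heart rate must be positive")
    if bpm < BRADYCARDIA_BPM:
        return "bradycardia"
    if bpm > TACHYCARDIA_BPM:
        return "tachycardia"
    return "normal"


def label_rr_periods(intervals: np.ndarray, t_obs: float | None = None) -> RRSeries:
    """Partition RR intervals into short/middle/long classes.

    The sorted intervals are split at every gap wider than
    ``RR_SPLIT_GAP_S``.  Sparse groups — fewer than max(2, 20%) of the
    intervals — are outliers (label 'O'): in practice these are the
    double-length artifacts left by an occasional missed beat, and they
    must not be allowed to masquerade as the rhythm's long period.  The
    surviving groups (merged down to at most three, smallest into its
    nearest neighbor) are labeled S/M/L in order of their means (a
    single group is M; two groups are S and L).
    """
    rr = np.asarray(intervals, dtype=float)
    if rr.size < 6:
        raise ValueError("need at least 6 RR intervals")
    order = np.argsort(rr)
    gaps = np.diff(rr[order])
    splits = np.flatnonzero(gaps > RR_SPLIT_GAP_S)
    bounds = [0, *(splits + 1), rr.size]
    groups = [order[a:b] for a, b in zip(bounds[:-1], bounds[1:])]

    min_count = max(2, int(np.ceil(0.2 * rr.size)))
    kept = [g for g in groups if g.size >= min_count]
    outliers = [g for g in groups if g.size < min_count]
    if not kept:  # pathological: everything sparse — fall back to one class
        kept, outliers = [order], []
    while len(kept) > 3:
        means = [rr[g].mean() for g in kept]
        i = int(np.argmin([g.size for g in kept]))
        j = min((k for k in range(len(kept)) if k != i), key=lambda k: abs(means[k] - means[i]))
        kept[j] = np.concatenate([kept[j], kept[i]])
        del kept[i]

    kept.sort(key=lambda g: rr[g].mean())
    names = {1: ["M"], 2: ["S", "L"], 3: ["S", "M", "L"]}[len(kept)]
    labels = np.empty(rr.size, dtype="<U1")
    for name, g in zip(names, kept):
        labels[g] = name
    for g in outliers:
        labels[g] = "O"
    return RRSeries(intervals=rr, labels=labels, t_obs=float(t_obs if t_obs is not None else rr.sum()))


def rrls_bar(series: RRSeries) -> float:
    """Average long-short difference:
    (sum of L intervals - sum of S intervals) / ((N_L + N_S)/2)."""
    n = series.n_long + series.n_short
    if n == 0:
        raise ValueError("no short or long intervals")
    diff = series._cls("L").sum() - series._cls("S").sum()
    return float(diff / (n / 2.0))


def detect_bigeminy_trigeminy(
    series: RRSeries,
    params: BigeminyParams | None = None,
    minute: int = 0,
    independent_trigeminy: bool = False,
) -> ArrhythmiaCall:
    """Bigeminy/trigeminy decision on one minute's RR structure.

    The trigeminy test is nested inside the bigeminy gate (bounded
    long-short difference with comparable long and short counts):
    within the gate, three ordered classes with comparable middle count
    mean trigeminy, a middle count differing from the long count means
    bigeminy.  ``independent_trigeminy`` evaluates the trigeminy
    signature without the gate.
    """
    params = params or BigeminyParams()
    n = series.intervals.size
    diff_ls = params.tolerance(n, "ls")
    diff_ms = params.tolerance(n, "ms")

    def trigeminy_signature() -> bool:
        if min(series.n_short, series.n_middle, series.n_long) == 0:
            return False
        ordered = series.mean("S") < series.mean("M") < series.mean("L")
        return ordered and abs(series.n_middle - series.n_short) < diff_ms

    evidence = {
        "n_short": series.n_short,
        "n_middle": series.n_middle,
        "n_long": series.n_long,
    }
    if series.n_long + series.n_short > 0:
        rrls = rrls_bar(series)
        evidence["rrls_bar"] = rrls
        gate = params.th_min < rrls < params.th_max and abs(series.n_long - series.n_short) < diff_ls
        if gate:
            if trigeminy_signature():
                return ArrhythmiaCall("trigeminy", minute, evidence)
            if abs(series.n_middle - series.n_long) >= diff_ls:
                return ArrhythmiaCall("bigeminy", minute, evidence)
    if independent_trigeminy and trigeminy_signature():
        return ArrhythmiaCall("trigeminy", minute, evidence)
    return ArrhythmiaCall("none", minute, evidence)


def detect_pvc(beat: Beat) -> str:
    """'PVC' iff the QRS is wide (> 120 ms) or the R is an abnormal
    (negative) peak; width-less beats are classified by polarity only."""
    if beat.qrs_width is not None and beat.qrs_width > PVC_QRS_WIDTH_S:
        return "PVC"
    if beat.r.polarity == "abnormal" and beat.r.amplitude < 0:
        return "PVC"
    return "N"


def _minute_bpm(beats: list[Beat], fs: float) -> float:
    rr = np.diff([b.r.index for b in beats]) / fs
    return 60.0 / float(rr.mean())


def detect_vt(beats: list[Beat], fs: float, minute: int = 0) -> ArrhythmiaCall:
    """VT: a run of >= 3 consecutive PVCs at a minute HR >= 100 bpm."""
    if len(beats) < 2:
        return ArrhythmiaCall("none", minute)
    bpm = _minute_bpm(beats, fs)
    run = longest = 0
    for b in beats:
        run = run + 1 if b.label == "PVC" else 0
        longest = max(longest, run)
    if longest >= VT_MIN_RUN and bpm >= VT_MIN_BPM:
        return ArrhythmiaCall("VT", minute, {"bpm": bpm, "longest_pvc_run": longest})
    return ArrhythmiaCall("none", minute, {"bpm": bpm, "longest_pvc_run": longest})


#: A "P" within this distance of the previous beat's T peak is the
#: merged P-T hump, not a separable P wave.
MERGED_PT_S = 0.060


def _lacks_separable_p(beat: Beat, prev: Beat | None, fs: float) -> bool:
    if beat.p_peak is None:
        return True
    if prev is not None and prev.t_peak is not None:
        return abs(beat.p_peak - prev.t_peak) <= MERGED_PT_S * fs
    return False


def detect_svt(beats: list[Beat], fs: float, minute: int = 0) -> ArrhythmiaCall:
    """SVT: 150-250 bpm, merged P-T waves (no separable P — or a "P"
    coincident with the previous T — for >= 70% of beats), and not
    PVC-dominated (which would be VT)."""
    if len(beats) < 2:
        return ArrhythmiaCall("none", minute)
    bpm = _minute_bpm(beats, fs)
    merged = sum(
        _lacks_separable_p(b, beats[i - 1] if i else None, fs) for i, b in enumerate(beats)
    ) / len(beats)
    pvc_frac = sum(1 for b in beats if b.label == "PVC") / len(beats)
    ev = {"bpm": bpm, "merged_p_fraction": merged, "pvc_fraction": pvc_frac}
    if SVT_MIN_BPM <= bpm <= SVT_MAX_BPM and merged >= SVT_MERGED_P_FRACTION and pvc_frac < 0.5:
        return ArrhythmiaCall("SVT", minute, ev)
    return ArrhythmiaCall("none", minute, ev)


def analyze_minute(
    record: EcgRecord,
    beats: list[Beat],
    minute: int = 0,
    bigeminy_params: BigeminyParams | None = None,
    af_severity_threshold: float = 0.6,
    compute_af: bool = True,
) -> list[ArrhythmiaCall]:
    """Apply every per-minute rule to one minute's delineated beats.

    Beats must already carry PVC labels (``detect_pvc``).  Returns all
    applicable calls; a minute with fewer than 2 beats yields a single
    none-call flagged for quality.
    """
    if len(beats) < 2:
        return [ArrhythmiaCall("none", minute, {"quality": "too_few_beats"})]
    fs = record.fs
    calls: list[ArrhythmiaCall] = []

    bpm = _minute_bpm(beats, fs)
    rate = classify_rate(bpm)
    if rate != "normal":
        calls.append(ArrhythmiaCall(rate, minute, {"bpm": bpm}))

    geminy = ArrhythmiaCall("none", minute)
    rr = np.diff([b.r.index for b in beats]) / fs
    if rr.size >= 6:
        series = label_rr_periods(rr)
        geminy = detect_bigeminy_trigeminy(series, bigeminy_params, minute)
        if geminy.type != "none":
            calls.append(geminy)

    vt = detect_vt(beats, fs, minute)
    svt = ArrhythmiaCall("none", minute)
    if vt.type == "VT":
        calls.append(vt)
    else:
        svt = detect_svt(beats, fs, minute)
        if svt.type == "SVT":
            calls.append(svt)

    n_pvc = sum(1 for b in beats if b.label == "PVC")
    if n_pvc and geminy.type == "none" and vt.type != "VT":
        calls.append(ArrhythmiaCall("PVC", minute, {"n_pvc": n_pvc}))

    # AF is the fallback explanation of an irregular minute: a structured
    # rhythm already accounts for the RR irregularity the severity score
    # keys on, so it takes precedence.
    structured = geminy.type != "none" or vt.type == "VT" or svt.type == "SVT"
    if compute_af and not structured and len(beats) >= 4:
        from .af import compute_af_features  # deferred: af imports this module's types

        fs_set = compute_af_features(record, beats)
        if fs_set.severity >= af_severity_threshold:
            calls.append(ArrhythmiaCall("AF", minute, {"severity": fs_set.severity}))

    if not calls:
        calls.append(ArrhythmiaCall("none", minute, {"bpm": bpm}))
    return calls
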