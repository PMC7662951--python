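"""End-to-end analysis: detect, delineate, label, classify, summarize."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .af import compute_af_features
from .arrhythmia import ArrhythmiaCall, BigeminyParams, analyze_minute, detect_pvc
from .fiducials import Beat, delineate_beat
from .hrv import HrvFreqDomain, HrvTimeDomain, freq_domain, time_domain
from .records import EcgRecord
from .rpeaks import REFRACTORY_S, RPeak, detect_r_peaks
from .windows import derive_window_plan


@dataclass
class AnalysisConfig:
    """Tunable constants of the full pipeline (CLI ``--config`` keys)."""

    particle_time_s: float = 4.0
    n_particle_times: int = 3
    refractory_s: float = REFRACTORY_S
    match_tolerance_s: float = 0.150
    bigeminy: BigeminyParams = field(default_factory=BigeminyParams)
    af_severity_threshold: float = 0.6


@dataclass
class AnalysisResult:
    peaks: list[RPeak]
    beats: list[Beat]
    minute_calls: dict[int, list[ArrhythmiaCall]]
    hrv_time: HrvTimeDomain | None
    hrv_freq: HrvFreqDomain | None
    af_features: "object | None"  # AfFeatureSet for records >= 1 min


def delineate_all(record: EcgRecord, peaks: list[RPeak]) -> list[Beat]:
    """Delineate every detected beat and attach its PVC/N label."""
    beats: list[Beat] = []
    for i, p in enumerate(peaks):
        beat = delineate_beat(
            record, p,
            prev_r=peaks[i - 1] if i > 0 else None,
            next_r=peaks[i + 1] if i + 1 < len(peaks) else None,
        )
        beat.label = detect_pvc(beat)
        beats.append(beat)
    return beats


def analyze_record(record: EcgRecord, config: AnalysisConfig | None = None) -> AnalysisResult:
    """Run the whole pipeline over a record.

    Arrhythmia rules are applied per whole minute (a trailing partial
    minute is not classified); HRV and AF features are computed over
    the full record when it is long enough.
    """
    config = config or AnalysisConfig()
    plan = derive_window_plan(record.fs, config.particle_time_s, config.n_particle_times)
    peaks = detect_r_peaks(record, plan, config.refractory_s)
    beats = delineate_all(record, peaks)

    minute_calls: dict[int, list[ArrhythmiaCall]] = {}
    n_minutes = int(record.duration // 60.0)
    for m in range(n_minutes):
        lo, hi = m * 60.0 * record.fs, (m + 1) * 60.0 * record.fs
        in_minute = [b for b in beats if lo <= b.r.index < hi]
        minute_calls[m] = analyze_minute(
            record, in_minute, m,
            bigeminy_params=config.bigeminy,
            af_severity_threshold=config.af_severity_threshold,
        )

    rr = np.diff([b.r.index for b in beats]) / record.fs if len(beats) > 1 else np.array([])
    hrv_t = time_domain(rr) if rr.size >= 2 else None
    hrv_f = None
    if rr.size >= 2 and rr.sum() >= 60.0:
        hrv_f = freq_domain(rr)
    af = None
    if len(beats) >= 4 and record.duration >= 60.0:
        af = compute_af_features(record, beats)
    return AnalysisResult(
        peaks=peaks,
        beats=beats,
        minute_calls=minute_calls,
        hrv_time=hrv_t,
        hrv_freq=hrv_f,
        af_features=af,
    )
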