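"""Five-feature atrial-fibrillation scoring and polar visualization.

AF is read off five normalized features averaged over at least one
minute: AA (atrial activity — the P-wave triangular area, low in AF),
HR (mean beats per minute), SD (the product of the Poincare axes SD1
and SD2, high for irregular RR), CPHB (one minus the probability of the
modal RR-histogram bin), and OSC (short-time spectral power in the
5-10.83 Hz fibrillatory band, QRS intervals excluded).  Each feature is
mapped to [0, 1] with fixed physiological min/max constants and their
mean is the severity score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .fiducials import Beat, p_wave_area
from .hrv import rr_histogram
from .records import EcgRecord

PA_ALPHA_S = 0.4   # time of one ECG-paper grid (s)
PA_BETA = 10.0     # area ratio control factor
BPM_MAX, BPM_MIN = 100.0, 0.0
MSD_MAX, MSD_MIN = 0.01, 0.0   # s^2
CPHB_MAX, CPHB_MIN = 1.0, 0.0
OSC_MAX, OSC_MIN = 15.0, 0.0
#: Fibrillatory band (Hz): 300-650 atrial waves per minute.
FIB_BAND_HZ = (5.0, 650.0 / 60.0)
#: Calibration: raw OSC = mean in-band spectrogram power (mV^2) x this.
OSC_SCALE = 1.0e3
STFT_WINDOW_S = 1.0


@dataclass
class AfFeatureSet:
    """Raw averages and their normalized [0,1] values; severity is the
    mean of the five normalized features."""

    aa: float
    hr: float
    sd: float
    cphb: float
    osc: float
    pa_avg: float
    bpm_avg: float
    msd_avg: float
    cphb_avg: float
    osc_avg: float

    @property
    def severity(self) -> float:
        return float(np.mean([self.aa, self.hr, self.sd, self.cphb, self.osc]))

    @property
    def normalized(self) -> dict[str, float]:
        return {"AA": self.aa, "HR": self.hr, "SD": self.sd, "CPHB": self.cphb, "OSC": self.osc}


def pa_max(fs: float, alpha: float = PA_ALPHA_S, beta: float = PA_BETA) -> float:
    """Maximum P-wave triangular area in grid units squared:
    (1/beta) * (3*alpha*F) * (2*alpha*F) / 2, the base and height of the
    largest admissible P wave on the grid."""
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    return (3.0 * alpha * fs) * (2.0 * alpha * fs) / 2.0 / beta


def poincare_msd(rr: np.ndarray) -> tuple[float, float, float]:
    """Poincare plot axes: SD1 (short axis), SD2 (long axis), and their
    product MSD.

    SD1^2 = var(successive differences)/2;
    SD2^2 = 2 var(rr) - var(successive differences)/2, floored at 0.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("need at least 3 RR intervals")
    dvar = float(np.var(np.diff(rr)))
    sd1 = float(np.sqrt(dvar / 2.0))
    sd2_sq = 2.0 * float(np.var(rr)) - dvar / 2.0
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    return sd1, sd2, sd1 * sd2


#: Shortest non-QRS segment (s) worth a periodogram.
MIN_OSC_SEGMENT_S = 0.15


def osc(
    samples: np.ndarray,
    fs: float,
    qrs_spans: list[tuple[int, int]] | None = None,
    band: tuple[float, float] = FIB_BAND_HZ,
    scale: float = OSC_SCALE,
) -> float:
    """Raw OSC: average short-time spectral power in the fibrillatory band.

    With ``qrs_spans`` (half-open sample ranges) the signal is split into
    its non-QRS segments and each gets its own Hann-window periodogram;
    the in-band powers are averaged weighted by segment length.  Working
    per segment keeps the broadband QRS energy out of the estimate
    without splicing artifacts.  Without spans a short-time spectrogram
    (1 s Hann windows, 50% overlap) of the whole signal is averaged.
    Returns in-band power (mV^2) times the calibration scale.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        return 0.0
    segments: list[np.ndarray]
    if qrs_spans:
        keep = np.ones(x.size, dtype=bool)
        for a, b in qrs_spans:
            keep[max(0, a):min(x.size, b)] = False
        min_n = int(MIN_OSC_SEGMENT_S * fs)
        segments = []
        edges = np.flatnonzero(np.diff(np.r_[0, keep.astype(int), 0]))
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a >= min_n:
                segments.append(x[a:b])
        if not segments:
            return 0.0
    else:
        segments = [x]

    total_power = 0.0
    total_len = 0
    for seg in segments:
        seg = seg - seg.mean()
        nperseg = min(seg.size, int(round(STFT_WINDOW_S * fs)))
        freqs, _, sxx = sps.spectrogram(
            seg, fs=fs, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, scaling="density",
        )
        mask = (freqs >= band[0]) & (freqs <= band[1])
        if not mask.any() or sxx.size == 0:
            continue
        band_power = float(np.trapezoid(sxx[mask, :], freqs[mask], axis=0).mean())
        total_power += band_power * seg.size
        total_len += seg.size
    if total_len == 0:
        return 0.0
    return float(total_power / total_len * scale)


def normalize_features(
    pa_avg: float,
    bpm_avg: float,
    msd_avg: float,
    cphb_avg: float,
    osc_avg: float,
    fs: float,
) -> AfFeatureSet:
    """Map raw feature averages to normalized [0,1] values.

    AA = (PAmax - PAavg)/(PAmax - PAmin); HR, SD, CPHB, OSC are linear
    maps with the fixed constants; every value is clipped to [0,1].
    """
    clip = lambda v: float(np.clip(v, 0.0, 1.0))
    pamax = pa_max(fs)
    return AfFeatureSet(
        aa=clip((pamax - pa_avg) / (pamax - 0.0)),
        hr=clip((bpm_avg - BPM_MIN) / (BPM_MAX - BPM_MIN)),
        sd=clip((msd_avg - MSD_MIN) / (MSD_MAX - MSD_MIN)),
        cphb=clip((cphb_avg - CPHB_MIN) / (CPHB_MAX - CPHB_MIN)),
        osc=clip((osc_avg - OSC_MIN) / (OSC_MAX - OSC_MIN)),
        pa_avg=float(pa_avg),
        bpm_avg=float(bpm_avg),
        msd_avg=float(msd_avg),
        cphb_avg=float(cphb_avg),
        osc_avg=float(osc_avg),
    )


def compute_af_features(record: EcgRecord, beats: list[Beat]) -> AfFeatureSet:
    """Full AF feature extraction for one analysis period (>= 1 min of
    beats is the intended use; shorter periods are computed as-is).

    PA is averaged over delineated beats, BPM/MSD/CPHB over the RR
    series, and OSC over the record with QRS intervals excised.
    """
    if len(beats) < 4:
        raise ValueError("need at least 4 beats for AF features")
    fs = record.fs
    rr = np.diff([b.r.index for b in beats]) / fs
    pa_avg = float(np.mean([p_wave_area(record, b) for b in beats]))
    bpm_avg = 60.0 / float(rr.mean())
    _, _, msd = poincare_msd(rr)
    counts, _ = rr_histogram(rr)
    cphb_avg = 1.0 - counts.max() / rr.size  # 1 - PHB = 1 - 1/HTI
    margin = round(0.02 * fs)  # keep QRS edge slopes out of the segments
    spans = []
    for b in beats:
        a = b.q_onset if b.q_onset is not None else b.r.index - round(0.06 * fs)
        z = b.s_offset if b.s_offset is not None else b.r.index + round(0.06 * fs)
        spans.append((a - margin, z + 1 + margin))
    osc_avg = osc(record.samples, fs, qrs_spans=spans)
    return normalize_features(pa_avg, bpm_avg, msd, cphb_avg, osc_avg, fs)


def polar_visualization_data(fs_set: AfFeatureSet) -> tuple[list[tuple[float, float]], float]:
    """Polar plot data: the five normalized features at angles
    90 + 72k degrees (AA, HR, SD, CPHB, OSC order) with radius equal to
    the value, plus the shoelace area of the resulting pentagon."""
    values = [fs_set.aa, fs_set.hr, fs_set.sd, fs_set.cphb, fs_set.osc]
    angles = [np.deg2rad(90.0 + 72.0 * k) for k in range(5)]
    points = [(float(np.rad2deg(a)), float(v)) for a, v in zip(angles, values)]
    xs = np.array([v * np.cos(a) for a, v in zip(angles, values)])
    ys = np.array([v * np.sin(a) for a, v in zip(angles, values)])
    area = 0.5 * abs(float(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))))
    return points, area
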