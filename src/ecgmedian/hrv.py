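"""Time- and frequency-domain heart-rate-variability indices.

Time domain: mean/std of RR and HR, NN50 and pNN50 (adjacent RR
differences strictly greater than 50 ms), RMSSD, the triangular index
HTI (total intervals over the modal histogram count, 1/128 s bins), its
reciprocal PHB, and TINN (base width of the least-squares triangle fit
to the RR histogram).

Frequency domain: the RR tachogram is resampled to an even 4 Hz grid by
cubic interpolation and a Welch spectrum integrated over the standard
bands — VLF 0-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz.  Total power
is the sum of the three bands, so band percentages always sum to 100
when any power is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal as sps

NN50_THRESHOLD_S = 0.050
HIST_BIN_S = 1.0 / 128.0
RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 120.0
VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class HrvTimeDomain:
    rr_mean: float
    rr_std: float
    hr_mean: float
    hr_std: float
    nn50: int
    pnn50: float
    rmssd: float
    hti: float
    tinn: float
    phb: float


@dataclass
class HrvFreqDomain:
    vlf_power: float
    lf_power: float
    hf_power: float
    vlf_pct: float
    lf_pct: float
    hf_pct: float
    lf_hf: float
    degenerate: bool = False


def rr_histogram(rr: np.ndarray, bin_s: float = HIST_BIN_S) -> tuple[np.ndarray, np.ndarray]:
    """RR histogram on the fixed 1/128 s grid; returns (counts, bin centers)."""
    rr = np.asarray(rr, dtype=float)
    lo = int(np.floor(rr.min() / bin_s))
    hi = int(np.floor(rr.max() / bin_s)) + 1
    edges = np.arange(lo, hi + 1) * bin_s
    counts, _ = np.histogram(rr, bins=edges)
    centers = edges[:-1] + bin_s / 2.0
    return counts, centers


def _tinn(counts: np.ndarray, centers: np.ndarray, bin_s: float) -> float:
    """Least-squares triangular fit to the histogram; returns M - N (s).

    The triangle rises from 0 at N to the modal count at the modal bin X
    and falls to 0 at M; N and M range over the bin grid (padded by one
    bin) and the pair minimizing the squared error is chosen.
    """
    x_idx = int(np.argmax(counts))
    peak = counts[x_idx]
    # pad one empty bin each side so the triangle can close
    counts = np.r_[0, counts, 0]
    centers = np.r_[centers[0] - bin_s, centers, centers[-1] + bin_s]
    x_idx += 1
    grid = np.arange(counts.size)
    best = (np.inf, bin_s)
    for n_i in range(0, x_idx):
        for m_i in range(x_idx + 1, counts.size):
            q = np.zeros_like(counts, dtype=float)
            up = slice(n_i, x_idx + 1)
            q[up] = peak * (grid[up] - n_i) / (x_idx - n_i)
            down = slice(x_idx, m_i + 1)
            q[down] = peak * (m_i - grid[down]) / (m_i - x_idx)
            err = float(((q - counts) ** 2).sum())
            if err < best[0] - 1e-12:
                best = (err, centers[m_i] - centers[n_i])
    return best[1]


def time_domain(rr: np.ndarray) -> HrvTimeDomain:
    """Time-domain HRV statistics of an RR series (seconds)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    diffs = np.diff(rr)
    nn50 = int((np.abs(diffs) > NN50_THRESHOLD_S).sum())
    counts, centers = rr_histogram(rr)
    hti = rr.size / counts.max()
    hr = 60.0 / rr
    return HrvTimeDomain(
        rr_mean=float(rr.mean()),
        rr_std=float(rr.std(ddof=1)),
        hr_mean=float(hr.mean()),
        hr_std=float(hr.std(ddof=1)),
        nn50=nn50,
        pnn50=float(nn50 / diffs.size * 100.0),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        hti=float(hti),
        tinn=float(_tinn(counts, centers, HIST_BIN_S)),
        phb=float(1.0 / hti),
    )


def freq_domain(rr: np.ndarray, rr_times: np.ndarray | None = None) -> HrvFreqDomain:
    """Frequency-domain HRV from the RR tachogram.

    ``rr_times`` are the times (s) of the beats ending each interval;
    by default the cumulative sum of rr.  Requires >= 60 s of signal.
    Powers are in ms^2.  A zero-variance tachogram is degenerate: all
    powers zero, lf/hf reported as 0 with the flag set.
    """
    rr = np.asarray(rr, dtype=float)
    t = np.cumsum(rr) if rr_times is None else np.asarray(rr_times, dtype=float)
    if t.size != rr.size:
        raise ValueError("rr_times must match rr in length")
    span = t[-1] - t[0]
    if span < 60.0:
        raise ValueError(f"need >= 60 s of RR data, got {span:.1f} s")
    rr_ms = rr * 1000.0
    grid = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    tach = interpolate.CubicSpline(t, rr_ms)(grid)
    nperseg = min(tach.size, int(WELCH_SEGMENT_S * RESAMPLE_HZ))
    freqs, psd = sps.welch(tach, fs=RESAMPLE_HZ, nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    total = vlf + lf + hf
    degenerate = total <= 0 or hf <= 0
    pct = (lambda p: p / total * 100.0) if total > 0 else (lambda p: 0.0)
    return HrvFreqDomain(
        vlf_power=vlf,
        lf_power=lf,
        hf_power=hf,
        vlf_pct=pct(vlf),
        lf_pct=pct(lf),
        hf_pct=pct(hf),
        lf_hf=0.0 if degenerate else lf / hf,
        degenerate=degenerate,
    )
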