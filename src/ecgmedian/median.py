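"""Variance-adaptive median filtering.

Within each sliding window a running median M of the signal S is computed
with a per-sample half-width r chosen from the local variance: high
variance (the QRS complex) gets the widest filter, flat baseline the
narrowest, and moderate variance (P/T waves) the basic size.  The
difference signal D = |S - M| then concentrates the QRS energy while the
filter, being wide exactly where the QRS is, leaves little of the R wave
in M.

All sizes derive from the sampling rate F: the basic half-width is
L = F/60 and the increment C = F/120, both rounded to the nearest
integer with a floor of 1.  The variance range [vmin, vmax] of the
window is split into three uniform sections; r is L-C, L or L+C
according to the section the local variance falls in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .windows import SlidingWindow


@dataclass
class FilterParams:
    """Adaptive-filter size constants for one window.

    L and C are half-widths in samples; vmin/vmax bound the local
    variance (mV^2) observed in the window and dv = vmax - vmin.
    """

    L: int
    C: int
    vmin: float = 0.0
    vmax: float = 0.0

    @property
    def dv(self) -> float:
        return self.vmax - self.vmin

    @classmethod
    def from_sampling_rate(cls, fs: float) -> "FilterParams":
        L = max(1, round(fs / 60.0))
        C = max(1, round(fs / 120.0))
        return cls(L=L, C=C)


@dataclass
class FilteredWindow:
    """Adaptive-median output for one window: M, D = |S - M|, and the
    per-sample half-size trace."""

    M: np.ndarray
    D: np.ndarray
    r_trace: np.ndarray
    params: FilterParams


def local_variance(samples: np.ndarray, L: int) -> np.ndarray:
    """Population variance over a centered neighborhood of half-width L.

    The neighborhood is 2L+1 samples, edge-replicated.  Computed as
    E[x^2] - E[x]^2 via uniform filters.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if L < 1:
        raise ValueError("half-width L must be >= 1")
    size = 2 * int(L) + 1
    mean = ndimage.uniform_filter1d(x, size=size, mode="nearest")
    mean_sq = ndimage.uniform_filter1d(x * x, size=size, mode="nearest")
    return np.maximum(mean_sq - mean * mean, 0.0)


def select_filter_size(v: float | np.ndarray, params: FilterParams) -> int | np.ndarray:
    """Map local variance to a filter half-width.

    The window's variance range is divided into three uniform sections:
    [vmin, vmin+dv/3) -> L-C, [vmin+dv/3, vmin+2dv/3) -> L, and
    [vmin+2dv/3, vmax] -> L+C.  A degenerate range (dv = 0) yields L.
    """
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr < params.vmin - 1e-12) or np.any(v_arr > params.vmax + 1e-12):
        raise ValueError("variance outside the window's [vmin, vmax] range")
    L, C = params.L, params.C
    if params.dv <= 0:
        r = np.full_like(v_arr, L, dtype=int)
    else:
        lo = params.vmin + params.dv / 3.0
        hi = params.vmin + 2.0 * params.dv / 3.0
        r = np.where(v_arr < lo, L - C, np.where(v_arr < hi, L, L + C))
    if np.isscalar(v) or v_arr.ndim == 0:
        return int(r)
    return r


def adaptive_median_filter(window: SlidingWindow, fs: float) -> FilteredWindow:
    """Apply the variance-adaptive median filter to one window.

    The half-size trace is computed from the variance at the basic size L
    and frozen; the median at sample i spans 2*r_trace[i]+1 samples with
    edge replication.  D = |S - M|.
    """
    S = np.asarray(window.samples, dtype=float)
    params = FilterParams.from_sampling_rate(fs)
    max_width = 2 * (params.L + params.C) + 1
    if S.size <= max_width:
        raise ValueError(
            f"window of {S.size} samples shorter than the maximal filter ({max_width})"
        )
    v = local_variance(S, params.L)
    # Dilate the variance by the basic half-width so every sample of a
    # high-variance complex (including the apex, whose own centered
    # window sees a locally symmetric, low-variance neighborhood at
    # coarse sampling rates) inherits the flank variance and with it the
    # wide filter the QRS is meant to get.
    v = ndimage.maximum_filter1d(v, size=2 * params.L + 1, mode="nearest")
    params.vmin = float(v.min())
    params.vmax = float(v.max())
    r_trace = np.asarray(select_filter_size(v, params), dtype=int)

    # one full running median per candidate size, then a per-sample pick
    M = np.empty_like(S)
    for r in np.unique(r_trace):
        filtered = ndimage.median_filter(S, size=2 * int(r) + 1, mode="nearest")
        mask = r_trace == r
        M[mask] = filtered[mask]
    D = np.abs(S - M)
    return FilteredWindow(M=M, D=D, r_trace=r_trace, params=params)
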