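"""Beat-detection scoring against reference annotations.

Detections are matched one-to-one to reference beats within a tolerance
window (150 ms by default); the usual beat-detection metrics follow:
sensitivity Se = TP/(TP+FN), positive predictivity +P = TP/(TP+FP) and
detection error rate DER = (FP+FN)/(TP+FN), all in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

MATCH_TOLERANCE_S = 0.150


@dataclass
class EvalResult:
    total: int
    tp: int
    fn: int
    fp: int
    se: float
    p_plus: float
    der: float


def _round2(x: float) -> float:
    """Round half-up to 2 decimals, as printed detection tables do."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def match_beats(
    detected: np.ndarray,
    reference: np.ndarray,
    fs: float,
    tolerance_s: float = MATCH_TOLERANCE_S,
) -> tuple[int, int, int]:
    """Greedy one-to-one nearest matching within +/- tolerance.

    Both index lists must be sorted.  Returns (TP, FN, FP).
    """
    det = np.asarray(detected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    tol = tolerance_s * fs
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for r in ref:
        # candidate detections within tolerance, nearest first
        lo = np.searchsorted(det, r - tol)
        hi = np.searchsorted(det, r + tol, side="right")
        cands = [k for k in range(lo, hi) if not used[k]]
        if cands:
            k = min(cands, key=lambda k: abs(det[k] - r))
            used[k] = True
            tp += 1
    fn = ref.size - tp
    fp = det.size - tp
    return tp, fn, fp


def metrics(total: int, fn: int, fp: int) -> EvalResult:
    """Score from counts: total reference beats, misses and false alarms."""
    if total <= 0:
        raise ValueError("need a positive number of reference beats")
    if fn < 0 or fp < 0 or fn > total:
        raise ValueError("invalid counts")
    tp = total - fn
    se = tp / (tp + fn) * 100.0
    p_plus = tp / (tp + fp) * 100.0 if tp + fp > 0 else 0.0
    der = (fp + fn) / (tp + fn) * 100.0
    return EvalResult(
        total=total,
        tp=tp,
        fn=fn,
        fp=fp,
        se=_round2(se),
        p_plus=_round2(p_plus),
        der=_round2(der),
    )


def evaluate_detections(
    detected: np.ndarray,
    reference: np.ndarray,
    fs: float,
    tolerance_s: float = MATCH_TOLERANCE_S,
) -> EvalResult:
    """Match then score in one step."""
    tp, fn, fp = match_beats(detected, reference, fs, tolerance_s)
    return metrics(int(tp + fn), int(fn), int(fp))
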