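"""Reading and writing ECG records and beat annotations.

The portable interchange format is a two-column CSV (time in seconds,
amplitude in mV) with a declared or inferred sampling rate.  WFDB
(PhysioNet) records are supported when the optional ``wfdb`` package is
installed; it is only needed for external-database validation, never by
the synthetic pipeline.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import EcgRecord
from .rpeaks import RPeak

#: MIT-style annotation symbols that denote beats (vs rhythm/noise marks).
BEAT_SYMBOLS = frozenset("NLRejAaJSVEF/fQ")


def read_csv(path: str | Path, fs: float | None = None, record_id: str | None = None) -> EcgRecord:
    """Load a two-column (time, amplitude) CSV.

    The sampling rate is taken from ``fs`` if given, else inferred from
    the median time step.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected a two-column CSV: time, amplitude")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    amps = df.iloc[:, 1].to_numpy(dtype=float)
    if fs is None:
        steps = np.diff(times)
        if steps.size == 0 or np.median(steps) <= 0:
            raise ValueError("cannot infer sampling rate from the time column")
        fs = 1.0 / float(np.median(steps))
    return EcgRecord(samples=amps, fs=float(fs), record_id=record_id or Path(path).stem)


def write_csv(record: EcgRecord, path: str | Path) -> None:
    """Write a record as a two-column (time, amplitude) CSV."""
    pd.DataFrame({"time_s": record.times, "amplitude_mv": record.samples}).to_csv(path, index=False)


def write_annotations_csv(peaks: list[RPeak], fs: float, path: str | Path) -> None:
    """Export detections: sample index, time, WFDB-style symbol, amplitude."""
    pd.DataFrame(
        {
            "sample": [p.index for p in peaks],
            "time_s": [p.time for p in peaks],
            "symbol": ["N" if p.polarity == "normal_positive" else "V" for p in peaks],
            "amplitude_mv": [p.amplitude for p in peaks],
        }
    ).to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df["sample"].to_numpy(dtype=int), list(df["symbol"].astype(str))


def _require_wfdb():
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "WFDB support requires the optional 'wfdb' package "
            "(pip install ecgmedian[wfdb]); CSV input needs no extras"
        ) from exc
    return wfdb


def read_wfdb(path: str | Path, channel: int = 0, annotator: str = "atr") -> EcgRecord:
    """Load a WFDB record (and its beat annotations, if present).

    Non-beat annotation symbols (rhythm changes, artifact marks, ...)
    are excluded from the reference beats.
    """
    wfdb = _require_wfdb()
    path = str(path)
    rec = wfdb.rdrecord(path)
    samples = np.asarray(rec.p_signal)[:, channel]
    ann_samples = ann_symbols = None
    try:
        ann = wfdb.rdann(path, annotator)
    except FileNotFoundError:
        ann = None
    if ann is not None:
        keep = [i for i, s in enumerate(ann.symbol) if s in BEAT_SYMBOLS]
        ann_samples = np.asarray(ann.sample)[keep]
        ann_symbols = [ann.symbol[i] for i in keep]
    return EcgRecord(
        samples=samples,
        fs=float(rec.fs),
        record_id=Path(path).stem,
        ann_samples=ann_samples,
        ann_symbols=ann_symbols,
    )


def write_wfdb(record: EcgRecord, directory: str | Path) -> None:
    """Write a record (and annotations) in WFDB format; needs ``wfdb``."""
    wfdb = _require_wfdb()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wfdb.wrsamp(
        record.record_id or "record",
        fs=record.fs,
        units=["mV"],
        sig_name=["ECG"],
        p_signal=record.samples[:, None],
        write_dir=str(directory),
    )
    if record.ann_samples is not None and record.ann_samples.size:
        wfdb.wrann(
            record.record_id or "record",
            "atr",
            np.asarray(record.ann_samples),
            symbol=list(record.ann_symbols),
            write_dir=str(directory),
        )
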