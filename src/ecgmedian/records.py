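"""The in-memory ECG container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EcgRecord:
    """A sampled single-lead ECG.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in millivolts.
    fs : float
        Sampling rate in samples per second.
    record_id : str
        Free-form identifier (file stem, database record name, ...).
    ann_samples : ndarray of int, optional
        Reference beat annotations as 0-based sample indices,
        strictly increasing.
    ann_symbols : list of str, optional
        One beat symbol per annotation ('N', 'V', ...).
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""
    ann_samples: np.ndarray | None = None
    ann_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.ann_samples is not None:
            self.ann_samples = np.asarray(self.ann_samples, dtype=int)
            if self.ann_samples.size and (
                np.any(np.diff(self.ann_samples) <= 0)
                or self.ann_samples[0] < 0
                or self.ann_samples[-1] >= self.samples.size
            ):
                raise ValueError("annotations must be strictly increasing and in range")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs
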