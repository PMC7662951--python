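"""Seeded parametric ECG generator for every rhythm class under test.

Beats are sums of Gaussian lobes (P, Q, R, S, T) placed on a zero
baseline at rhythm-dependent RR intervals:

* ``sinus``      — constant RR from the configured BPM (optional jitter);
* ``bigeminy``   — alternating 0.6 s / ~0.9 s RR, every other beat a PVC;
* ``trigeminy``  — repeating 0.55 / 0.78 / 0.90 s RR, every third a PVC;
* ``pvc_random`` — sinus with a random fraction of PVCs (early beat plus
  compensatory pause);
* ``vt``         — 0.40 s RR, all beats PVCs;
* ``svt``        — 0.32 s RR with the P wave merged into the T wave;
* ``af``         — lognormal RR (CV >= 0.15), no P waves, band-limited
  5-11 Hz fibrillatory noise.

PVC morphology is a wide (> 120 ms) negative QRS without a P wave.
Optional 0.2 Hz baseline wander, white measurement noise and isolated
QRS-like impulse artifacts complete the test conditions.  Identical
configurations and seeds give identical output, and beat times are
drawn in continuous time so records generated at different sampling
rates share their ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .records import EcgRecord

RHYTHMS = ("sinus", "bigeminy", "trigeminy", "pvc_random", "vt", "svt", "af")

#: Gaussian lobe table: name -> (center offset s, width sigma s, amplitude mV)
NORMAL_COMPONENTS = {
    "p": (-0.200, 0.025, 0.15),
    "q": (-0.030, 0.010, -0.10),
    "r": (0.000, 0.015, 1.00),
    "s": (0.030, 0.020, -0.20),
    "t": (0.250, 0.050, 0.30),
}
# A PVC is a wide slurred complex with a fast apex: a broad flat negative
# base (> 120 ms at half height) carrying a sharp central spike whose slew
# matches a normal QRS — the feature real PVCs share with normal beats and
# the one the median-difference detector keys on.
PVC_COMPONENTS = {
    "b0": (-0.066, 0.020, -0.75),
    "b1": (-0.033, 0.020, -0.75),
    "b2": (0.000, 0.020, -0.75),
    "b3": (0.033, 0.020, -0.75),
    "b4": (0.066, 0.020, -0.75),
    "spike": (0.000, 0.011, -0.85),  # apex slew comparable to a normal R
    "t": (0.320, 0.060, 0.45),
}
SVT_COMPONENTS = {  # P merged into a late, broad T hugging the next QRS
    "q": (-0.030, 0.010, -0.10),
    "r": (0.000, 0.015, 1.00),
    "s": (0.030, 0.020, -0.20),
    "t": (0.160, 0.050, 0.30),  # a single mid-gap hump: T with P merged in
}

FIRST_BEAT_S = 0.5
END_MARGIN_S = 0.4
WANDER_HZ = 0.2
FIB_BAND_HZ = (5.0, 11.0)
ARTIFACT_WIDTH_S = 0.010
ARTIFACT_AMP_MV = 0.8


@dataclass(frozen=True)
class BeatMorphology:
    """Per-beat waveform description: named Gaussian lobes."""

    components: dict[str, tuple[float, float, float]]
    label: str = "N"

    @classmethod
    def normal(cls) -> "BeatMorphology":
        return cls(dict(NORMAL_COMPONENTS), "N")

    @classmethod
    def pvc(cls) -> "BeatMorphology":
        return cls(dict(PVC_COMPONENTS), "PVC")

    @classmethod
    def svt_merged(cls) -> "BeatMorphology":
        return cls(dict(SVT_COMPONENTS), "N")


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the study conditions each
    rhythm class is tested under."""

    fs: float = 250.0
    duration: float = 60.0
    rhythm: str = "sinus"
    bpm: float = 75.0
    rr_pattern: list[float] | None = None
    pvc_fraction: float = 0.1
    fib_amplitude: float = 0.15
    wander_amplitude: float = 0.0
    artifact_rate: float = 0.0
    noise_sd: float = 0.01
    rr_jitter_sd: float = 0.0
    af_mean_rr: float = 0.6
    af_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 50:
            raise ValueError("sampling rate must be >= 50 samples/s")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rhythm not in RHYTHMS:
            raise ValueError(f"unknown rhythm {self.rhythm!r}; choose from {RHYTHMS}")


@dataclass
class AnnotatedRecord:
    """Generator output: the record plus its ground truth."""

    record: EcgRecord
    truth_times: np.ndarray          # R centers (s)
    truth_labels: list[str]          # 'N' / 'PVC' per beat
    truth_fiducials: list[dict[str, float]]  # absolute lobe centers (s)

    @property
    def truth_samples(self) -> np.ndarray:
        return np.round(self.truth_times * self.record.fs).astype(int)


def synth_beat(morph: BeatMorphology, fs: float, span: tuple[float, float] = (-0.4, 0.5)) -> np.ndarray:
    """Render one beat on its own grid (for inspection and tests)."""
    t = np.arange(span[0], span[1], 1.0 / fs)
    wave = np.zeros_like(t)
    for center, width, amp in morph.components.values():
        if width <= 0:
            raise ValueError("component widths must be positive")
        wave += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return wave


def _rhythm_schedule(cfg: SynthConfig, rng: np.random.Generator) -> tuple[list[float], list[str]]:
    """Draw the RR sequence (s) and per-beat labels for the rhythm."""
    usable = cfg.duration - FIRST_BEAT_S - END_MARGIN_S
    if cfg.rr_pattern is not None:
        pat = list(cfg.rr_pattern)
        if not pat or min(pat) <= 0 or pat[0] > max(usable, 0):
            raise ValueError("rr_pattern incompatible with the configured duration")
        rrs, labels, total, k = [], ["N"], 0.0, 0
        while total + pat[k % len(pat)] <= usable:
            total += pat[k % len(pat)]
            rrs.append(pat[k % len(pat)])
            labels.append("N")
            k += 1
        return rrs, labels

    rrs: list[float] = []
    labels: list[str] = ["N"]
    total = 0.0

    def push(rr: float, label: str) -> bool:
        nonlocal total
        if total + rr > usable:
            return False
        rrs.append(rr)
        labels.append(label)
        total += rr
        return True

    if cfg.rhythm == "sinus":
        base = 60.0 / cfg.bpm
        while push(base + (rng.normal(0, cfg.rr_jitter_sd) if cfg.rr_jitter_sd else 0.0), "N"):
            pass
    elif cfg.rhythm == "bigeminy":
        labels[0] = "N"
        k = 0
        while True:
            # short RR into the PVC, jittered long RR back to the normal beat
            rr = 0.6 if k % 2 == 0 else 0.9 + rng.uniform(-0.05, 0.05)
            if not push(rr, "PVC" if k % 2 == 0 else "N"):
                break
            k += 1
    elif cfg.rhythm == "trigeminy":
        pattern = [0.55, 0.78, 0.90]
        k = 0
        while push(pattern[k % 3], "PVC" if k % 3 == 0 else "N"):
            k += 1
    elif cfg.rhythm == "pvc_random":
        base = 60.0 / cfg.bpm
        pending_pause = False
        while True:
            if pending_pause:
                ok = push(1.25 * base, "N")
                pending_pause = False
            elif rng.random() < cfg.pvc_fraction:
                ok = push(0.75 * base, "PVC")
                pending_pause = True
            else:
                ok = push(base, "N")
            if not ok:
                break
    elif cfg.rhythm == "vt":
        labels[0] = "PVC"
        while push(0.40, "PVC"):
            pass
    elif cfg.rhythm == "svt":
        while push(0.32, "N"):
            pass
    elif cfg.rhythm == "af":
        sigma = np.sqrt(np.log(1.0 + cfg.af_cv**2))
        mu = np.log(cfg.af_mean_rr) - sigma**2 / 2.0
        while push(float(np.clip(rng.lognormal(mu, sigma), 0.35, 1.5)), "N"):
            pass
    return rrs, labels


def _morphology_for(cfg: SynthConfig, label: str) -> BeatMorphology:
    if label == "PVC":
        return BeatMorphology.pvc()
    if cfg.rhythm == "svt":
        return BeatMorphology.svt_merged()
    if cfg.rhythm == "af":
        comps = {k: v for k, v in NORMAL_COMPONENTS.items() if k != "p"}
        return BeatMorphology(comps, "N")
    return BeatMorphology.normal()


def synth_record(cfg: SynthConfig) -> AnnotatedRecord:
    """Generate one annotated record from the configuration.

    Deterministic for a fixed (config, seed); RR draws happen in
    continuous time before rasterization, so ground-truth beat times do
    not depend on the sampling rate.
    """
    rng = np.random.default_rng(cfg.seed)
    rrs, labels = _rhythm_schedule(cfg, rng)
    beat_times = FIRST_BEAT_S + np.r_[0.0, np.cumsum(rrs)]

    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    fiducials: list[dict[str, float]] = []
    for bt, label in zip(beat_times, labels):
        morph = _morphology_for(cfg, label)
        fid = {}
        for name, (center, width, amp) in morph.components.items():
            c = bt + center
            fid[name] = c
            lo = max(0, int((c - 5 * width) * cfg.fs))
            hi = min(n, int((c + 5 * width) * cfg.fs) + 1)
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
        fiducials.append(fid)

    if cfg.rhythm == "af" and cfg.fib_amplitude > 0:
        white = rng.standard_normal(n)
        nyq = cfg.fs / 2.0
        b, a = sps.butter(3, [FIB_BAND_HZ[0] / nyq, min(FIB_BAND_HZ[1], 0.95 * nyq) / nyq], btype="band")
        fib = sps.filtfilt(b, a, white)
        fib *= (cfg.fib_amplitude / np.sqrt(2.0)) / max(fib.std(), 1e-12)
        x += fib
    if cfg.wander_amplitude > 0:
        x += cfg.wander_amplitude * np.sin(2 * np.pi * WANDER_HZ * t + rng.uniform(0, 2 * np.pi))
    if cfg.artifact_rate > 0:
        n_art = rng.poisson(cfg.artifact_rate * cfg.duration / 60.0)
        for at in rng.uniform(0.0, cfg.duration, size=n_art):
            x += ARTIFACT_AMP_MV * np.exp(-0.5 * ((t - at) / ARTIFACT_WIDTH_S) ** 2)
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, size=n)

    truth_samples = np.round(beat_times * cfg.fs).astype(int)
    record = EcgRecord(
        samples=x,
        fs=cfg.fs,
        record_id=f"synth-{cfg.rhythm}-seed{cfg.seed}",
        ann_samples=truth_samples,
        ann_symbols=["V" if lab == "PVC" else "N" for lab in labels],
    )
    return AnnotatedRecord(
        record=record,
        truth_times=beat_times,
        truth_labels=list(labels),
        truth_fiducials=fiducials,
    )
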