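# Methods

## The detection model

`ecgmedian` detects R peaks by subtraction rather than by enhancement:
a running median M of the signal S preserves the slow waves (P, T,
baseline wander) while rejecting the narrow QRS, so the difference
D = |S − M| concentrates QRS energy on a near-zero background. Every
size constant derives from the sampling rate F, which is what makes the
same pipeline valid from 128 to 500 samples/s:

| constant | value | role |
|---|---|---|
| basic median half-width L | round(F/60), floor 1 | ≈ 33 ms window |
| increment C | round(F/120), floor 1 | adaptive step |
| max-filter width | round(F/8) | ≈ 125 ms candidate plateau |
| sliding window | Tp·N_Tp = 12 s (Tp = 4 s, N_Tp = 3) | processing unit |
| window step | Tp·(N_Tp−1) = 8 s | 4 s overlap |

The filter is *variance-adaptive*: within each 12 s window the local
variance (population variance over ±L samples, edge-replicated) is
mapped to a half-width r ∈ {L−C, L, L+C} by splitting the window's
variance range [vmin, vmax] into three uniform sections anchored at
vmin. High variance — the QRS — draws the widest filter and is
therefore suppressed hardest in M, maximizing D exactly where the beat
is.

Two numerical choices matter here:

* **Variance dilation.** Before the tertile mapping, the variance trace
  is dilated by a running maximum over ±L. The apex sample of a peak
  sees a locally symmetric neighborhood whose variance can be *low*, so
  without dilation the apex can draw the smallest filter — an artifact
  that appears at coarse rates (128 Hz) where the QRS spans only a few
  samples, and that cost ~9% sensitivity there. Dilation gives the
  whole complex the flank variance, which is the mapping's intent.
* **Frozen trace.** r is selected once from the variance at the basic
  size L; the median filter is then applied with that per-sample size.
  There is no iterative re-estimation.

Candidate intervals are maximal runs where the running maximum of D
(width F/8, edge-replicated) reaches the adaptive threshold — the mean
of the top 50% (by value) of the envelope samples, recomputed per
window. One peak is taken per run at the argmax of D, snapped to the
extremum of the original signal within ±25 ms. A peak is a normal
(positive) R if its original amplitude exceeds the window mean,
abnormal (negative R / PVC) otherwise; ties go to abnormal. Peaks
closer than a 200 ms refractory period (the physiological minimum RR)
keep the larger D, both within a window and when overlapping windows
are merged.

The top-50% threshold has a knowable failure mode: at very high rates
(RR ≈ 0.3 s) the envelope is mostly plateau, the threshold hugs the
mean plateau height, and beats whose D falls a little below the mean
are lost — a few percent on noisy SVT. The per-window
adaptation otherwise keeps weak normal beats detectable next to large
ectopics.

## Delineation

Fiducial searches run on a 10 ms moving-average smoothed copy.

* **Q onset / S offset**: from the steepest point of each R flank
  (the apex itself has near-zero slope), walk outward until the slope
  magnitude falls below 10% of the flank peak *and* the amplitude has
  returned within 20% of the R excursion over the local baseline
  (median over ±0.3 s). The amplitude guard carries the walk across
  the flat top of wide slurred complexes without running into
  neighboring waves; search span ±150 ms.
* **P**: most prominent interior extremum in
  [q_onset − 300 ms, q_onset − 40 ms], clipped to 120 ms after the
  previous R; prominence ≥ 5% of |R| or the P is absent. P onset and
  offset are slope walks outward from each flank's steepest point at a
  gentler 5% threshold (the P slope is an order of magnitude below the
  QRS slope).
* **T**: most prominent interior extremum in
  [s_offset + 80 ms, s_offset + 400 ms], clipped 60 ms before the next
  R; with no interior extremum (fast rhythms push the apex to the
  window edge) the largest excursion from the window's far-edge value
  is taken.

A "P" within 60 ms of the previous beat's T peak is treated as the
merged P–T hump, not a separable P — the basis of the SVT rule.

The P-wave area PA is the triangle over (p_onset, p_peak, p_offset)
with the peak height corrected to the onset–offset chord, base in
samples and height in amplitude grid units of 0.1 mV (one standard ECG
paper box). The analytic ceiling PAmax = β⁻¹(3αF)(2αF)/2 with α = 0.4 s
(one time grid) and β = 10 is on the same sample × grid scale; on
generator P waves the triangle reproduces the Gaussian-lobe area within
~10%.

## Per-minute arrhythmia rules

All rules run on whole minutes (the processing unit for rate, VT, SVT
and AF decisions; PVC is per beat). A trailing partial minute is not
classified.

* **Rate**: bradycardia < 60 bpm, tachycardia > 100 bpm, strict
  inequalities; HR = 60 / mean RR of the minute.
* **PVC**: QRS width > 120 ms, or an abnormal-polarity peak with
  negative amplitude.
* **Bigeminy / trigeminy**: the sorted RR intervals are split at every
  gap > 50 ms; groups holding fewer than max(2, 20%) of the intervals
  are outliers (label 'O') — in practice the double-length artifacts
  of an occasional missed beat, which must not claim the long-period
  label. Surviving groups (merged to at most three) are labeled S/M/L
  by mean. With RRLS̄ = (ΣRR_L − ΣRR_S)/((N_L+N_S)/2), the gate is
  0.10 s < RRLS̄ < 0.60 s and |N_L − N_S| < DiffLS; inside the gate,
  three ordered classes with |N_M − N_S| < DiffMS mean trigeminy, a
  middle count differing from the long count means bigeminy. DiffLS =
  DiffMS = max(2, 10% of intervals). The trigeminy-inside-bigeminy
  nesting is exposed; a flag also allows the independent three-class
  signature.
* **VT**: a run of ≥ 3 consecutive PVC-labeled beats at minute
  HR ≥ 100 bpm. Tested before SVT.
* **SVT**: 150 ≤ HR ≤ 250 bpm, ≥ 70% of beats lack a separable P
  (absent, or coincident with the previous T), and under 50% PVC beats
  (else the rhythm is ventricular).
* **AF**: severity ≥ 0.6 (below), emitted only when no structured
  rhythm (bigeminy/trigeminy/VT/SVT) already explains the minute — the
  severity score keys on RR irregularity those rhythms produce by
  construction. Severity is computed and reported regardless.

## HRV

Time domain: NN50 counts successive differences strictly > 50 ms;
pNN50 = NN50/(n−1)·100; RMSSD is the RMS of successive differences.
The RR histogram uses fixed 1/128 s bins (the standard HRV convention);
HTI = n / modal bin count, PHB = 1/HTI, and TINN is the base width of
the least-squares triangle fit over the binned histogram (peak pinned
at the modal bin, base endpoints searched over the padded bin grid).
TINN's fixed bin grid means it is only approximately scale-equivariant
and the fit collapses on sparse flat histograms.

Frequency domain: the tachogram (RR in ms vs beat time) is resampled to
4 Hz by cubic spline and a Welch spectrum (120 s segments or the whole
record if shorter, 50% overlap) is integrated over VLF 0–0.04 Hz,
LF 0.04–0.15 Hz, HF 0.15–0.40 Hz. Total power is defined as the sum of
the three bands, so percentages always total 100; LF/HF is reported as
0 with a degeneracy flag when HF power vanishes (constant RR).

## AF severity

Five features, each averaged over ≥ 1 min, normalized with fixed
constants and clipped to [0, 1]; severity is their mean.

| feature | raw quantity | normalization |
|---|---|---|
| AA | mean triangular P area (grid units²) | (PAmax − PA)/PAmax |
| HR | mean bpm | /100 |
| SD | Poincaré SD1·SD2 (s²) | /0.01 |
| CPHB | 1 − modal-bin probability | /1 |
| OSC | fibrillatory-band power | /15 |

SD1² = var(ΔRR)/2 and SD2² = 2·var(RR) − var(ΔRR)/2 (floored at 0),
the standard ellipse identities for the 45°-rotated Poincaré cloud.

OSC is the length-weighted mean of Hann-periodogram power integrated
over 5–10.83 Hz (300–650 atrial waves/min), computed per non-QRS
segment (QRS spans excised with a 20 ms margin; segments ≥ 150 ms).
Working per segment keeps broadband QRS energy and splice artifacts out
of the band and avoids harmonic pile-up from fast periodic T waves.
The conventional ceiling OSCmax = 15 is tied to signal units by a
calibration constant (raw OSC = mean in-band power in mV² × 10³),
exposed as `OSC_SCALE` since the reference units are conventional.

The polar view places the five normalized features at 90° + k·72°,
radius = value; the pentagon's shoelace area is a single severity
visual (all-ones area = (5/2)·sin 72° ≈ 2.378).

## The synthetic generator

Beats are sums of Gaussian lobes on a zero baseline; RR schedules are
drawn in continuous time before rasterization, so ground truth is
sampling-rate-independent and byte-reproducible per (config, seed).
Defaults: P (−0.20 s, σ 25 ms, 0.15 mV), Q (−0.03, 10 ms, −0.10),
R (0, 15 ms, 1.0), S (+0.03, 20 ms, −0.20), T (+0.25, 50 ms, 0.30);
white measurement noise σ = 0.01 mV.

Rhythm schedules: sinus at the configured BPM (default 75, optional
Gaussian RR jitter, off by default); bigeminy alternating 0.6 s /
0.9 ± 0.05 s with every second beat a PVC; trigeminy cycling
0.55/0.78/0.90 s with every third beat a PVC; random PVCs (10%) with a
0.75·RR coupling interval and 1.25·RR compensatory pause; VT at 0.40 s
RR, all PVCs; SVT at 0.32 s RR with a single mid-gap hump (P merged
into T); AF with lognormal RR (mean 0.6 s, CV 0.2, clipped to
0.35–1.5 s), absent P, and 5–11 Hz band-passed fibrillatory noise of
0.15 mV nominal amplitude (coarse fibrillation). Optional 0.2 Hz
sinusoidal wander and isolated 10 ms QRS-like impulse artifacts.

The PVC shape deserves a note. A median filter passes monotone edges
and plateaus untouched — only peaks narrower than the filter window
produce a difference signal — so a smooth wide Gaussian "PVC" is
invisible to this detector *and* draws the smallest adaptive size (its
local variance is moderate). Real large PVCs are not smooth: they are
broad slurred complexes with a fast apex. The generator's PVC is
therefore a flat negative base (half-height width 125 ms) carrying a
sharp central spike with normal-QRS slew, which the detector captures
at 100% on clean 250 Hz test minutes.

What the generator does not emulate: beat-to-beat morphology variation,
respiration-coupled HRV, muscle-noise spectra, electrode motion other
than sinusoidal wander, multi-lead geometry, atrial flutter, and the
fine/coarse fibrillatory amplitude taxonomy. Tests passing on this
generator show the pipeline implements its rules correctly at any
sampling rate; they do not certify clinical performance on measured
ECG, for which the WFDB entry points (optional `wfdb` extra) exist.

## Degenerate inputs and tie-breaks

Flat windows (zero threshold) yield no peaks. Dv = 0 maps every sample
to the basic size L, making the filter a plain running median. An
amplitude exactly at the window mean classifies abnormal. Equal-D
refractory conflicts keep the earlier peak. Records shorter than the
maximal filter raise; trailing stream remnants shorter than 2 s are
dropped. SD2² is floored at zero; empty S/L classes make the
bigeminy gate unevaluable (no call) rather than an error.

## Problem sizes used in the checks

The bundled verification runs use 60 s minutes (20 seeds per rhythm
class), 5 min sinus records per sampling rate, and 100 AF/sinus pairs
for severity separation — sizes at which every decision rule operates
on its intended processing unit.
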