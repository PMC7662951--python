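import numpy as np
import pytest

from ecgmedian import (
    EcgRecord,
    SynthConfig,
    detect_r_peaks,
    normalize_features,
    osc,
    pa_max,
    poincare_msd,
    polar_visualization_data,
    synth_record,
)
from ecgmedian.af import compute_af_features
from ecgmedian.pipeline import delineate_all


class TestPaMax:
    def test_known_values(self):
        # (1/10) * (3*0.4*F) * (2*0.4*F) / 2
        assert pa_max(250) == pytest.approx(3000.0)
        assert pa_max(360) == pytest.approx(6220.8)

    def test_zero_alpha(self):
        assert pa_max(250, alpha=0.0) == 0.0

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            pa_max(0)


def rotated_cloud_sds(rr):
    """Oracle: rotate the (rr_i, rr_{i+1}) cloud by 45 degrees and take
    the axis standard deviations."""
    x, y = rr[:-1], rr[1:]
    short_axis = (y - x) / np.sqrt(2)
    long_axis = (x + y) / np.sqrt(2)
    return float(np.std(short_axis)), float(np.std(long_axis))


class TestPoincare:
    def test_constant_rr_degenerate(self):
        sd1, sd2, msd = poincare_msd(np.full(50, 0.8))
        assert sd1 == pytest.approx(0.0, abs=1e-12)
        assert sd2 == pytest.approx(0.0, abs=1e-12)
        assert msd == pytest.approx(0.0, abs=1e-12)

    def test_alternating_pattern_matches_rotation_oracle(self):
        rr = np.array([0.6, 0.9] * 30)
        sd1, sd2, msd = poincare_msd(rr)
        o_sd1, _ = rotated_cloud_sds(rr)
        assert sd1 == pytest.approx(o_sd1, rel=0.02)

    def test_independent_jitter_gives_sd1_near_sigma(self):
        rng = np.random.default_rng(0)
        sigma = 0.03
        rr = 0.8 + rng.normal(0, sigma, size=10_000)
        sd1, sd2, _ = poincare_msd(rr)
        assert sd1 == pytest.approx(sigma, rel=0.05)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            poincare_msd(np.array([0.8, 0.8]))


class TestOsc:
    def test_zero_signal(self):
        assert osc(np.zeros(15000), 250.0) == 0.0

    def test_monotone_in_fibrillatory_amplitude(self):
        t = np.arange(0, 60, 1 / 250)
        values = []
        for amp in (0.05, 0.10, 0.20):
            x = amp * np.sin(2 * np.pi * 7.0 * t)
            values.append(osc(x, 250.0))
        assert values[0] < values[1] < values[2]

    def test_added_in_band_noise_increases_power(self, sinus_record):
        x = sinus_record.record.samples
        t = np.arange(x.size) / 250
        with_noise = x + 0.1 * np.sin(2 * np.pi * 7.0 * t)
        assert osc(with_noise, 250.0) > osc(x, 250.0)

    def test_qrs_exclusion_reduces_broadband_leakage(self, sinus_record):
        peaks = detect_r_peaks(sinus_record.record)
        spans = [(p.index - 25, p.index + 25) for p in peaks]
        with_qrs = osc(sinus_record.record.samples, 250.0)
        without_qrs = osc(sinus_record.record.samples, 250.0, qrs_spans=spans)
        assert without_qrs < with_qrs


class TestNormalization:
    def test_aa_endpoints(self):
        fs = 250.0
        full = normalize_features(pa_max(fs), 60, 0.002, 0.5, 5, fs)
        empty = normalize_features(0.0, 60, 0.002, 0.5, 5, fs)
        assert full.aa == 0.0
        assert empty.aa == 1.0

    def test_hr_linear_map(self):
        fs_set = normalize_features(0.0, 50, 0.0, 0.0, 0.0, 250.0)
        assert fs_set.hr == pytest.approx(0.5)

    def test_values_clipped_to_unit_interval(self):
        fs_set = normalize_features(-10.0, 250.0, 0.5, 2.0, 100.0, 250.0)
        for v in fs_set.normalized.values():
            assert 0.0 <= v <= 1.0

    def test_severity_of_printed_feature_vector(self):
        # a severe-AF feature vector averages to its printed severity
        vec = [0.70, 0.95, 1.0, 0.91, 1.0]
        fs_set = normalize_features(0, 0, 0, 0, 0, 250.0)
        fs_set.hr, fs_set.cphb, fs_set.sd, fs_set.aa, fs_set.osc = vec
        assert round(fs_set.severity, 2) == 0.91


class TestPolarVisualization:
    def _feature_set(self, values):
        fs_set = normalize_features(0, 0, 0, 0, 0, 250.0)
        fs_set.aa, fs_set.hr, fs_set.sd, fs_set.cphb, fs_set.osc = values
        return fs_set

    def test_all_zero_area(self):
        _, area = polar_visualization_data(self._feature_set([0, 0, 0, 0, 0]))
        assert area == 0.0

    def test_unit_pentagon_area(self):
        _, area = polar_visualization_data(self._feature_set([1, 1, 1, 1, 1]))
        assert area == pytest.approx(2.5 * np.sin(np.deg2rad(72)))

    def test_area_monotone_in_each_feature(self):
        base = [0.5] * 5
        _, a0 = polar_visualization_data(self._feature_set(base))
        for k in range(5):
            bumped = list(base)
            bumped[k] = 0.8
            _, a1 = polar_visualization_data(self._feature_set(bumped))
            assert a1 > a0


class TestDiscrimination:
    def test_af_severity_exceeds_sinus(self):
        wins = 0
        for seed in range(10):
            pair = {}
            for rhythm in ("af", "sinus"):
                ann = synth_record(SynthConfig(fs=250, duration=60, rhythm=rhythm, seed=seed))
                peaks = detect_r_peaks(ann.record)
                beats = delineate_all(ann.record, peaks)
                pair[rhythm] = compute_af_features(ann.record, beats).severity
            wins += pair["af"] > pair["sinus"]
        assert wins >= 10  # clear separation on every seeded pair here

    def test_amplitude_rescaling_invariance_split(self, af_record):
        # HR/SD/CPHB come from RR times only: invariant under amplitude
        # scaling; AA and OSC are amplitude-coupled by design.
        peaks = detect_r_peaks(af_record.record)
        beats = delineate_all(af_record.record, peaks)
        a = compute_af_features(af_record.record, beats)
        scaled = EcgRecord(af_record.record.samples * 2.0, 250.0)
        peaks2 = detect_r_peaks(scaled)
        beats2 = delineate_all(scaled, peaks2)
        b = compute_af_features(scaled, beats2)
        assert b.hr == pytest.approx(a.hr, abs=0.02)
        assert b.cphb == pytest.approx(a.cphb, abs=0.05)
        assert b.sd == pytest.approx(a.sd, abs=0.05)
        assert b.osc_avg > a.osc_avg  # quadruples in power, modulo clipping
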