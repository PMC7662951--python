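import numpy as np
import pytest

from ecgmedian import (
    Beat,
    BigeminyParams,
    SynthConfig,
    classify_rate,
    detect_bigeminy_trigeminy,
    detect_pvc,
    detect_svt,
    detect_vt,
    label_rr_periods,
    rrls_bar,
    synth_record,
)
from ecgmedian.arrhythmia import RRSeries, analyze_minute
from ecgmedian.pipeline import analyze_record
from ecgmedian.rpeaks import RPeak


class TestClassifyRate:
    @pytest.mark.parametrize(
        "bpm, expected",
        [(55, "bradycardia"), (59.9, "bradycardia"), (60, "normal"),
         (100, "normal"), (100.1, "tachycardia"), (120, "tachycardia")],
    )
    def test_strict_boundaries(self, bpm, expected):
        assert classify_rate(bpm) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_rate(0)


class TestLabelRrPeriods:
    def test_bigeminy_pattern_two_classes(self):
        rr = np.array([0.6, 0.9] * 20)
        s = label_rr_periods(rr)
        assert (s.n_short, s.n_middle, s.n_long) == (20, 0, 20)

    def test_trigeminy_pattern_three_equal_classes(self):
        rr = np.array([0.55, 0.78, 0.90] * 15)
        s = label_rr_periods(rr)
        assert s.n_short == s.n_middle == s.n_long == 15
        assert s.mean("S") < s.mean("M") < s.mean("L")

    def test_constant_series_all_middle(self):
        s = label_rr_periods(np.full(20, 0.8))
        assert s.n_middle == 20 and s.n_short == s.n_long == 0

    def test_missed_beat_doubles_are_outliers(self):
        rr = np.array([0.6, 0.9] * 20 + [1.5] * 4)
        s = label_rr_periods(rr)
        assert (s.n_short, s.n_long) == (20, 20)
        assert (s.labels == "O").sum() == 4

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            label_rr_periods(np.array([0.8] * 5))


class TestRrlsBar:
    def _series(self, short, long, middle=()):
        rr = np.array(list(short) + list(middle) + list(long))
        labels = np.array(["S"] * len(short) + ["M"] * len(middle) + ["L"] * len(long))
        return RRSeries(intervals=rr, labels=labels, t_obs=float(rr.sum()))

    def test_direct_evaluation(self):
        assert rrls_bar(self._series([0.6, 0.6], [0.9, 0.9])) == pytest.approx(0.3)
        assert rrls_bar(self._series([0.5], [1.0])) == pytest.approx(0.5)

    def test_equal_sums_give_zero(self):
        assert rrls_bar(self._series([0.7, 0.7], [0.7, 0.7])) == pytest.approx(0.0)

    def test_empty_classes_rejected(self):
        with pytest.raises(ValueError):
            rrls_bar(self._series([], [], middle=[0.8] * 6))


class TestBigeminyTrigeminy:
    def test_alternating_pattern_is_bigeminy(self):
        s = label_rr_periods(np.array([0.6, 0.9] * 15))
        assert detect_bigeminy_trigeminy(s).type == "bigeminy"

    def test_three_period_pattern_is_trigeminy(self):
        s = label_rr_periods(np.array([0.55, 0.78, 0.90] * 20))
        assert detect_bigeminy_trigeminy(s).type == "trigeminy"

    def test_constant_rhythm_is_none(self):
        s = label_rr_periods(np.full(40, 0.8))
        assert detect_bigeminy_trigeminy(s).type == "none"

    def test_positive_bigeminy_has_comparable_counts(self):
        # mutual consistency: every positive call satisfies its own gate
        for seed in range(5):
            ann = synth_record(SynthConfig(fs=250, duration=60, rhythm="bigeminy", seed=seed))
            res = analyze_record(ann.record)
            for call in res.minute_calls[0]:
                if call.type == "bigeminy":
                    params = BigeminyParams()
                    n = call.evidence["n_short"] + call.evidence["n_middle"] + call.evidence["n_long"]
                    assert abs(call.evidence["n_long"] - call.evidence["n_short"]) < params.tolerance(n, "ls")

    def test_independent_trigeminy_flag(self):
        # out-of-gate three-class pattern: rrls_bar above th_max
        s = label_rr_periods(np.array([0.4, 0.8, 1.2] * 10))
        assert detect_bigeminy_trigeminy(s).type == "none"
        assert detect_bigeminy_trigeminy(s, independent_trigeminy=True).type == "trigeminy"


def _beat(label="N", qrs_width=0.08, polarity="normal_positive", amplitude=1.0, index=0):
    b = Beat(r=RPeak(index=index, time=index / 250.0, amplitude=amplitude, polarity=polarity))
    b.qrs_width = qrs_width
    b.label = label
    return b


class TestPvcVtSvt:
    def test_wide_qrs_is_pvc(self):
        assert detect_pvc(_beat(qrs_width=0.15)) == "PVC"

    def test_narrow_normal_beat(self):
        assert detect_pvc(_beat(qrs_width=0.08)) == "N"

    def test_negative_r_without_width_is_pvc(self):
        b = _beat(qrs_width=None, polarity="abnormal", amplitude=-0.5)
        assert detect_pvc(b) == "PVC"

    def _minute(self, labels, rr_s):
        beats = []
        idx = 0
        for lab in labels:
            beats.append(_beat(label=lab, index=idx))
            idx += int(rr_s * 250)
        return beats

    def test_long_pvc_run_at_high_rate_is_vt(self):
        beats = self._minute(["PVC"] * 10, 0.4)  # 150 bpm
        assert detect_vt(beats, 250).type == "VT"

    def test_couplet_is_not_vt(self):
        beats = self._minute(["N", "PVC", "PVC", "N"] * 10, 0.4)
        assert detect_vt(beats, 250).type == "none"

    def test_pvc_run_at_low_rate_is_not_vt(self):
        beats = self._minute(["PVC"] * 4 + ["N"] * 10, 0.75)  # 80 bpm
        assert detect_vt(beats, 250).type == "none"

    def test_svt_band_and_merged_p(self):
        beats = self._minute(["N"] * 60, 0.32)  # 187 bpm, no P anywhere
        assert detect_svt(beats, 250).type == "SVT"

    def test_below_band_not_svt(self):
        beats = self._minute(["N"] * 60, 0.43)  # ~140 bpm
        assert detect_svt(beats, 250).type == "none"

    def test_pvc_dominated_fast_rhythm_is_vt_not_svt(self):
        ann = synth_record(SynthConfig(fs=250, duration=60, rhythm="vt", seed=4))
        calls = [c.type for c in analyze_record(ann.record).minute_calls[0]]
        assert "VT" in calls and "SVT" not in calls


class TestAnalyzeMinute:
    def test_deterministic(self, bigeminy_record):
        a = analyze_record(bigeminy_record.record)
        b = analyze_record(bigeminy_record.record)
        assert [c.type for c in a.minute_calls[0]] == [c.type for c in b.minute_calls[0]]

    def test_too_few_beats_flagged(self, sinus_record):
        calls = analyze_minute(sinus_record.record, [], minute=0)
        assert calls[0].type == "none"
        assert calls[0].evidence.get("quality") == "too_few_beats"

    def test_clean_sinus_yields_no_calls(self, analyzed_sinus):
        assert [c.type for c in analyzed_sinus.minute_calls[0]] == ["none"]

    def test_vt_minute_also_tachycardic(self):
        ann = synth_record(SynthConfig(fs=250, duration=60, rhythm="vt", seed=2))
        calls = [c.type for c in analyze_record(ann.record).minute_calls[0]]
        assert "tachycardia" in calls and "VT" in calls
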