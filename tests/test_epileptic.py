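"""Interictal spike detection, myoclonus discrimination, artifacts, GTC."""

import warnings

import numpy as np
import pytest

from rippletherm.core import (
    ACTIVE,
    IMMOBILE,
    BaselineStats,
    DetectionParams,
    EpilepticEvent,
    StateSegments,
    TimeSeries,
)
from rippletherm.epileptic import (
    classify_myoclonic,
    detect_spike_candidates,
    locate_gtc,
    peri_event_average,
    reject_artifacts,
)
from rippletherm.preprocess import compute_baseline_stats, zscore
from rippletherm.synth import evaluate_detection

from conftest import truth_outside_gtc_guard

FS = 2048.0


def _z(values, fs=FS):
    return TimeSeries(values, fs, units="z")


class TestSpikeCandidates:
    def test_smooth_trace_yields_nothing(self, params):
        t = np.arange(int(2 * FS)) / FS
        a = _z(0.5 * np.sin(2 * np.pi * 1.0 * t))
        d = _z(0.5 * np.sin(2 * np.pi * 1.0 * t))
        assert detect_spike_candidates(a, d, params) == []

    def test_biphasic_transient_gives_one_aligned_event(self, params):
        n = int(2 * FS)
        a = np.zeros(n)
        d = np.zeros(n)
        c = n // 2
        a[c - 10:c + 10] = -8.0
        a[c] = -9.0
        d[c - 12:c + 12] = 20.0
        events = detect_spike_candidates(_z(a), _z(d), params)
        assert len(events) == 1
        assert events[0].trough_time == pytest.approx(c / FS, abs=1e-6)
        assert events[0].amplitude == pytest.approx(-9.0)

    def test_high_amplitude_but_slow_rise_rejected(self, params):
        n = int(2 * FS)
        a = np.full(n, 0.0)
        a[n // 2 - 100:n // 2 + 100] = 3.0
        d = np.full(n, 2.0)
        assert detect_spike_candidates(_z(a), _z(d), params) == []

    def test_dead_time_collapses_nearby_seeds(self, params):
        n = int(2 * FS)
        a = np.zeros(n)
        d = np.zeros(n)
        c = n // 2
        for off, amp in [(0, -6.0), (int(0.05 * FS), -9.0)]:  # 50 ms apart
            a[c + off] = amp
            d[c + off] = 20.0
        events = detect_spike_candidates(_z(a), _z(d), params)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(-9.0)


def _emg_trace(pre_level, post_level, t_event=1.0, duration=2.0, fs=FS):
    z = np.zeros(int(duration * fs))
    i = int(t_event * fs)
    w = int(0.1 * fs)
    z[i - w:i] = pre_level
    z[i + 1:i + w + 1] = post_level
    return _z(z, fs)


class TestClassifyMyoclonic:
    def test_fourfold_post_power_is_myoclonus(self, params):
        # recentered means: pre 0 -> 1, post 3 -> 4; ratio 4 > 2
        ev = EpilepticEvent(trough_time=1.0, amplitude=-10.0)
        out = classify_myoclonic(ev, _emg_trace(0.0, 3.0), params)
        assert out.event_class == "myoclonic"
        assert out.emg_ratio == pytest.approx(4.0, rel=1e-6)

    def test_equal_power_is_interictal(self, params):
        ev = EpilepticEvent(trough_time=1.0, amplitude=-10.0)
        out = classify_myoclonic(ev, _emg_trace(1.5, 1.5), params)
        assert out.event_class == "interictal_spike"
        assert out.emg_ratio == pytest.approx(1.0, rel=1e-6)

    def test_ratio_exactly_two_is_interictal(self, params):
        # strict >2: pre 0 -> 1, post 1 -> 2 gives exactly 2
        ev = EpilepticEvent(trough_time=1.0, amplitude=-10.0)
        out = classify_myoclonic(ev, _emg_trace(0.0, 1.0), params)
        assert out.event_class == "interictal_spike"
        assert out.emg_ratio == pytest.approx(2.0, rel=1e-6)

    def test_event_near_edge_left_unclassified_with_warning(self, params):
        ev = EpilepticEvent(trough_time=0.05, amplitude=-10.0)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = classify_myoclonic(ev, _emg_trace(0.0, 3.0), params)
        assert out.emg_ratio is None
        assert any("edge" in str(w.message) for w in rec)

    def test_invariant_to_global_emg_gain(self, params):
        # the ratio is formed on z-scored power, and z-scoring removes gain
        rng = np.random.default_rng(5)
        raw = rng.gamma(2.0, 1.0, int(2 * FS))
        raw[int(1.0 * FS):int(1.1 * FS)] += 25.0
        outs = []
        for gain in (1.0, 50.0):
            p = TimeSeries(raw * gain, FS, label="emg-power")
            stats = compute_baseline_stats(p, (0.0, 0.9), "emg-power",
                                           min_duration=0.0)
            ev = EpilepticEvent(trough_time=1.0, amplitude=-10.0)
            outs.append(classify_myoclonic(ev, zscore(p, stats), params))
        assert outs[0].emg_ratio == pytest.approx(outs[1].emg_ratio, rel=1e-9)
        assert outs[0].event_class == outs[1].event_class == "myoclonic"


def _states(duration, active=()):
    intervals = []
    cursor = 0.0
    for s, e in active:
        if s > cursor:
            intervals.append((cursor, s, IMMOBILE))
        intervals.append((s, e, ACTIVE))
        cursor = e
    if cursor < duration:
        intervals.append((cursor, duration, IMMOBILE))
    return StateSegments(intervals)


class TestRejectArtifacts:
    def _channels(self, n, deflect_at=(), amp=10.0, n_ch=2):
        chans = []
        for _ in range(n_ch):
            v = np.zeros(n)
            for t in deflect_at:
                v[int(t * FS)] = amp
            chans.append(_z(v))
        return chans

    def test_event_in_active_segment_is_artifact(self, params):
        n = int(4 * FS)
        events = [EpilepticEvent(trough_time=2.0, amplitude=-10.0),
                  EpilepticEvent(trough_time=3.5, amplitude=-10.0)]
        states = _states(4.0, active=[(1.5, 2.5)])
        out = reject_artifacts(events, self._channels(n, [2.0, 3.5]),
                               _z(np.zeros(n)), states, params)
        # exhaustive: exactly the events inside active intervals are flagged
        for ev in out:
            in_active = 1.5 <= ev.trough_time < 2.5
            assert (ev.event_class == "artifact") == in_active

    def test_isolated_single_channel_spike_retained(self, params):
        n = int(4 * FS)
        chans = self._channels(n, [], n_ch=2)
        chans[0].values[int(2.0 * FS)] = -12.0
        events = [EpilepticEvent(trough_time=2.0, amplitude=-12.0)]
        out = reject_artifacts(events, chans, _z(np.zeros(n)),
                               _states(4.0), params)
        assert out[0].event_class == "interictal_spike"

    def test_bilateral_deflection_with_preexisting_emg_is_artifact(self, params):
        n = int(4 * FS)
        emg = np.zeros(n)
        emg[int(1.2 * FS):int(2.4 * FS)] = 6.0  # elevated well before the spike
        events = [EpilepticEvent(trough_time=2.0, amplitude=-12.0)]
        out = reject_artifacts(events, self._channels(n, [2.0], amp=12.0),
                               _z(emg), _states(4.0), params)
        assert out[0].event_class == "artifact"

    def test_emg_starting_at_spike_is_not_artifact(self, params):
        # myoclonus: the EMG burst begins at the spike, not before it
        n = int(4 * FS)
        emg = np.zeros(n)
        emg[int(2.0 * FS):int(2.4 * FS)] = 6.0
        events = [EpilepticEvent(trough_time=2.0, amplitude=-12.0)]
        out = reject_artifacts(events, self._channels(n, [2.0], amp=12.0),
                               _z(emg), _states(4.0), params)
        assert out[0].event_class == "interictal_spike"

    def test_low_amplitude_candidate_is_morphology_reject(self, params):
        n = int(4 * FS)
        events = [EpilepticEvent(trough_time=2.0, amplitude=-1.2)]
        out = reject_artifacts(events, self._channels(n, []), _z(np.zeros(n)),
                               _states(4.0), params)
        assert out[0].event_class == "artifact"

    def test_override_takes_precedence(self, params):
        n = int(4 * FS)
        events = [EpilepticEvent(trough_time=2.0, amplitude=-12.0)]
        out = reject_artifacts(events, self._channels(n, []), _z(np.zeros(n)),
                               _states(4.0, active=[(1.5, 2.5)]), params,
                               overrides={2.0: "keep"})
        assert out[0].event_class == "interictal_spike"
        out = reject_artifacts(events, self._channels(n, []), _z(np.zeros(n)),
                               _states(4.0), params, overrides={2.0: "artifact"})
        assert out[0].event_class == "artifact"


class TestLocateGtc:
    def test_annotation_has_priority(self, params):
        assert locate_gtc({"gtc_onset": 900.0}) == 900.0

    def test_recovered_within_one_second_on_synthetic_sessions(self, ds_cohort):
        for bundle in ds_cohort:
            true_gtc = bundle.truth.times_of("gtc")
            assert true_gtc.size == 1
            assert bundle.result.gtc_onset is not None
            assert abs(bundle.result.gtc_onset - true_gtc[0]) < 1.0

    def test_wt_sessions_have_no_gtc(self, wt_trio):
        for bundle in wt_trio:
            assert bundle.result.gtc_onset is None
            assert bundle.truth.times_of("gtc").size == 0


class TestPeriEventAverage:
    def _transient(self, n, c, width=50, amp=5.0):
        v = np.zeros(n)
        v[c - width:c + width] = amp * np.hanning(2 * width)
        return v

    def test_identical_copies_average_to_the_transient(self):
        n = int(10 * FS)
        v = np.zeros(n)
        times = [2.0, 5.0, 8.0]
        for t in times:
            v += self._transient(n, int(t * FS))
        events = [EpilepticEvent(trough_time=t) for t in times]
        (avg,) = peri_event_average([TimeSeries(v, FS)], events, window=0.5)
        expected = self._transient(int(2 * 0.5 * FS) + 1, int(0.5 * FS))
        np.testing.assert_allclose(avg.values, expected, atol=1e-12)
        assert avg.start_time == pytest.approx(-0.5)

    def test_transient_plus_negation_cancel(self):
        n = int(10 * FS)
        v = self._transient(n, int(2 * FS)) - self._transient(n, int(6 * FS))
        events = [EpilepticEvent(trough_time=2.0), EpilepticEvent(trough_time=6.0)]
        (avg,) = peri_event_average([TimeSeries(v, FS)], events, window=0.5)
        np.testing.assert_allclose(avg.values, 0.0, atol=1e-12)

    def test_averaging_improves_snr_by_sqrt_n(self):
        rng = np.random.default_rng(6)
        n = int(220 * 512)
        fs = 512.0
        noise_sd = 1.0
        v = rng.standard_normal(n) * noise_sd
        times = np.arange(100) * 2.0 + 1.0
        for t in times:
            c = int(t * fs)
            v[c - 25:c + 25] += 5.0 * np.hanning(50)
        events = [EpilepticEvent(trough_time=t) for t in times]
        (avg,) = peri_event_average([TimeSeries(v, fs)], events, window=0.5)
        # residual noise SD should be ~ noise_sd / 10
        tail = avg.values[:100]  # away from the transient
        assert np.std(tail) < 2.0 * noise_sd / 10.0
        assert np.std(tail) > 0.0

    def test_zero_usable_events_is_error(self):
        ts = TimeSeries(np.zeros(1000), FS)
        with pytest.raises(ValueError, match="no events"):
            peri_event_average([ts], [EpilepticEvent(trough_time=0.01)], window=0.5)


class TestPipelineSpikeRecovery:
    def test_spike_recall_precision_on_cohort(self, ds_cohort):
        for bundle in ds_cohort:
            detected = [e for e in bundle.result.clean_epileptic
                        if e.event_class == "interictal_spike"]
            times = truth_outside_gtc_guard(bundle, "interictal_spike")
            from rippletherm.synth import GroundTruth, GroundTruthRecord
            truth = GroundTruth([GroundTruthRecord("interictal_spike", t)
                                 for t in times])
            score = evaluate_detection(truth, detected, tolerance=0.03,
                                       truth_type="interictal_spike")
            assert score.recall >= 0.9
            assert score.precision >= 0.9

    def test_myoclonus_classification_accuracy(self, ds_cohort):
        correct = total = 0
        for bundle in ds_cohort:
            detected = list(bundle.result.clean_epileptic)
            det_times = np.array([e.trough_time for e in detected])
            for kind in ("interictal_spike", "myoclonic"):
                for t in truth_outside_gtc_guard(bundle, kind):
                    if det_times.size == 0:
                        continue
                    j = int(np.argmin(np.abs(det_times - t)))
                    if abs(det_times[j] - t) <= 0.03:
                        total += 1
                        correct += detected[j].event_class == kind
        assert total >= 100
        assert correct / total >= 0.95

    def test_no_clean_event_inside_active_segment(self, ds_cohort):
        for bundle in ds_cohort:
            for ev in bundle.result.clean_epileptic:
                assert bundle.result.states.label_at(ev.trough_time) != ACTIVE
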