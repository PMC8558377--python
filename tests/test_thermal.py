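"""Temperature-binned aggregation, alignment, suppression, and trend fits."""

import numpy as np
import pytest

from rippletherm.core import (
    IMMOBILE,
    DetectionParams,
    EpilepticEvent,
    StateSegments,
    TimeSeries,
)
from rippletherm.thermal import (
    align_to_anchor,
    dwell_and_rate,
    feature_by_temperature,
    fit_sigmoid_trend,
    grand_average,
    onset_temperatures,
    pearson_trend,
    peri_event_rate,
    pre_post_rate_test,
    spectral_peak_frequency,
    spw_amplitude_split_test,
    temperature_bin_center,
    trend_and_group_stats,
)


def _temp(values, fs=10.0):
    return TimeSeries(np.asarray(values, dtype=float), fs, units="degC")


class _Ev:
    """Minimal event stub with a time and a temperature."""

    def __init__(self, time, temperature, **features):
        self.trough_time = time
        self.temperature = temperature
        for k, v in features.items():
            setattr(self, k, v)


def test_bin_convention_half_open_anchored_at_36():
    assert temperature_bin_center(37.25, 0.5) == pytest.approx(37.5)
    assert temperature_bin_center(37.2499, 0.5) == pytest.approx(37.0)
    assert temperature_bin_center(36.0, 0.25) == pytest.approx(36.0)
    np.testing.assert_allclose(temperature_bin_center([35.8, 38.74], 0.5),
                               [36.0, 38.5])


class TestDwellAndRate:
    def test_rate_is_count_over_dwell(self):
        temp = _temp(np.full(200, 37.0))  # 20 s at 37.0
        events = [EpilepticEvent(trough_time=0.1 * i, temperature=37.0)
                  for i in range(10)]
        bins = dwell_and_rate(events, temp, 0.5)
        assert len(bins) == 1
        assert bins[0].dwell_time == pytest.approx(20.0)
        assert bins[0].rate == pytest.approx(0.5)

    def test_constant_temperature_single_bin(self):
        temp = _temp(np.full(1000, 37.0))
        events = [EpilepticEvent(trough_time=10.0 * i + 5, temperature=37.0)
                  for i in range(5)]
        bins = dwell_and_rate(events, temp, 0.5)
        assert len(bins) == 1
        assert bins[0].bin_center == pytest.approx(37.0)
        assert bins[0].rate == pytest.approx(0.05)

    def test_homogeneous_events_on_ramp_recover_true_rate(self):
        # linear 36->40 degC over 400 s with Poisson events at 0.5 /s
        rng = np.random.default_rng(12)
        temp = _temp(36.0 + 4.0 * np.arange(4000) / 4000.0)
        times = np.sort(rng.uniform(0, 400, rng.poisson(0.5 * 400)))
        events = [EpilepticEvent(trough_time=t,
                                 temperature=temp.value_at(t)) for t in times]
        bins = dwell_and_rate(events, temp, 0.5)
        dwells = [b.dwell_time for b in bins if 36.5 <= b.bin_center <= 39.5]
        np.testing.assert_allclose(dwells, 50.0, rtol=0.05)
        rates = np.array([b.rate for b in bins if b.dwell_time > 20])
        assert np.all(np.abs(rates - 0.5) < 4 * np.sqrt(0.5 / 50.0))

    def test_conservation_of_counts_and_dwell(self):
        rng = np.random.default_rng(13)
        temp = _temp(36.0 + 2.0 * rng.random(3000))
        times = np.sort(rng.uniform(0, 300, 100))
        events = [EpilepticEvent(trough_time=t, temperature=temp.value_at(t))
                  for t in times]
        restrict = [(50.0, 250.0)]
        bins = dwell_and_rate(events, temp, 0.5, restrict=restrict)
        n_in = np.sum((times >= 50.0) & (times < 250.0))
        assert sum(b.event_count for b in bins) == n_in
        assert sum(b.dwell_time for b in bins) == pytest.approx(200.0, abs=0.1)

    def test_zero_dwell_bin_flagged_undefined(self):
        temp = _temp(np.full(100, 37.0))
        events = [EpilepticEvent(trough_time=5.0, temperature=39.0)]
        bins = dwell_and_rate(events, temp, 0.5)
        flagged = [b for b in bins if b.bin_center == pytest.approx(39.0)]
        assert len(flagged) == 1
        assert not flagged[0].defined
        assert np.isnan(flagged[0].rate)


class TestFeatureByTemperature:
    def test_uniform_feature_gives_zero_sem(self):
        events = [_Ev(i, 36.0 + 0.1 * i, frequency=150.0) for i in range(10)]
        bins = feature_by_temperature(events, "frequency", 0.25)
        for b in bins:
            assert b.mean_feature == pytest.approx(150.0)
            assert b.sem == 0.0

    def test_two_event_bin_mean_and_sem(self):
        events = [_Ev(0.0, 37.0, frequency=140.0), _Ev(1.0, 37.0, frequency=160.0)]
        (b,) = feature_by_temperature(events, "frequency", 0.25)
        assert b.mean_feature == pytest.approx(150.0)
        assert b.sem == pytest.approx(10.0)

    def test_linear_trend_recovered_from_bin_means(self):
        rng = np.random.default_rng(14)
        temps = rng.uniform(36.0, 39.0, 400)
        freqs = 135.0 + 8.0 * (temps - 36.0) + rng.normal(0, 2.0, temps.size)
        events = [_Ev(i, T, frequency=f) for i, (T, f) in
                  enumerate(zip(temps, freqs))]
        bins = feature_by_temperature(events, "frequency", 0.25)
        x = np.array([b.bin_center for b in bins])
        y = np.array([b.mean_feature for b in bins])
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(8.0, abs=1.0)


class TestSpectralPeak:
    def _session(self, freqs_by_half, seed=15):
        fs = 2048.0
        rng = np.random.default_rng(seed)
        half = int(60 * fs)
        x = rng.standard_normal(2 * half) * 5.0
        for k, f in enumerate(freqs_by_half):
            tt = np.arange(-0.02, 0.02, 1 / fs)
            wave = 40.0 * np.exp(-0.5 * (tt / 0.008) ** 2) * np.cos(2 * np.pi * f * tt)
            for c in np.arange(2.0, 58.0, 1.5):
                i = k * half + int(c * fs)
                x[i:i + wave.size] += wave
        lfp = TimeSeries(x, fs, units="uV")
        temp = _temp(np.concatenate([np.full(600, 36.2), np.full(600, 38.2)]))
        return lfp, temp

    def test_embedded_ripples_recovered(self):
        lfp, temp = self._session([175.0, 175.0])
        peaks = spectral_peak_frequency(lfp, temp, None)
        assert all(p.ok for p in peaks)
        for p in peaks:
            assert p.frequency == pytest.approx(175.0, abs=5.0)

    def test_white_noise_only_flagged(self):
        rng = np.random.default_rng(16)
        lfp = TimeSeries(rng.standard_normal(int(30 * 2048.0)), 2048.0)
        temp = _temp(np.full(300, 36.2))
        peaks = spectral_peak_frequency(lfp, temp, None)
        assert all(not p.ok for p in peaks)

    def test_two_bins_ordered(self):
        lfp, temp = self._session([140.0, 180.0])
        peaks = sorted(spectral_peak_frequency(lfp, temp, None),
                       key=lambda p: p.bin_center)
        assert peaks[0].frequency < peaks[1].frequency
        assert peaks[0].frequency == pytest.approx(140.0, abs=5.0)
        assert peaks[1].frequency == pytest.approx(180.0, abs=5.0)


class TestAlignToAnchor:
    def test_gtc_anchor_relative_times(self, params):
        temp = _temp(np.full(100, 37.0))
        al = align_to_anchor([890.0], temp, params, gtc_time=900.0)
        assert al.anchor_type == "gtc"
        assert al.relative_times[0] == pytest.approx(-10.0)

    def test_crossing_anchor_when_no_gtc(self, params):
        temp = _temp(np.linspace(36.0, 40.0, 4000))  # crosses 38.5 at 250 s
        al = align_to_anchor([250.0], temp, params, gtc_time=None)
        assert al.anchor_type == "temperature_crossing"
        assert al.relative_times[0] == pytest.approx(0.0, abs=0.5)

    def test_gtc_has_priority_over_crossing(self, params):
        temp = _temp(np.linspace(36.0, 40.0, 4000))
        al = align_to_anchor([0.0], temp, params, gtc_time=300.0)
        assert al.anchor_type == "gtc"
        assert al.anchor_time == 300.0

    def test_error_when_no_anchor(self, params):
        temp = _temp(np.full(100, 36.0))
        with pytest.raises(ValueError, match="anchor"):
            align_to_anchor([1.0], temp, params, gtc_time=None)


class TestOnsetTemperatures:
    def test_first_event_temperature_per_class(self):
        sessions = [[EpilepticEvent(trough_time=10.0, temperature=37.6),
                     EpilepticEvent(trough_time=20.0, temperature=38.0)]]
        out = onset_temperatures(sessions)
        assert out["interictal_spike"].mean == pytest.approx(37.6)
        assert out["myoclonic"] is None
        assert out["gtc"] is None

    def test_grand_average_and_sem(self):
        sessions = [
            [EpilepticEvent(trough_time=1.0, temperature=37.6)],
            [EpilepticEvent(trough_time=1.0, temperature=38.0)],
        ]
        out = onset_temperatures(sessions)
        assert out["interictal_spike"].mean == pytest.approx(37.8)
        assert out["interictal_spike"].sem == pytest.approx(0.2)


class TestPeriEventRate:
    def test_single_trigger_single_event_definition(self):
        centers, rates = peri_event_rate([10.1], [10.0], bin_width=0.25,
                                         window=1.0)
        j = int(np.argmin(np.abs(centers - 0.125)))
        assert rates[j] == pytest.approx(4.0)  # 1 event / 0.25 s / 1 trigger
        assert rates.sum() == pytest.approx(4.0)

    def test_homogeneous_events_give_flat_histogram(self):
        rng = np.random.default_rng(17)
        events = np.sort(rng.uniform(0, 2000, rng.poisson(2000)))  # 1 /s
        triggers = np.sort(rng.uniform(50, 1950, 60))
        centers, rates = peri_event_rate(events, triggers, duration=2000.0)
        np.testing.assert_allclose(rates, 1.0, atol=0.35)
        assert abs(np.mean(rates) - 1.0) < 0.1

    def test_zero_triggers_is_error(self):
        with pytest.raises(ValueError, match="trigger"):
            peri_event_rate([1.0], [], window=1.0)

    def test_suppression_recovered_from_cohort(self, ds_cohort):
        pooled_pre, pooled_post = [], []
        for bundle in ds_cohort:
            triggers = [e.trough_time for e in bundle.result.clean_epileptic]
            if not triggers:
                continue
            centers, rates = peri_event_rate(
                [r.start for r in bundle.result.ripple_events], triggers,
                duration=bundle.result.duration)
            pooled_pre.append(rates[centers < 0].mean())
            pooled_post.append(rates[centers > 0].mean())
        assert len(pooled_pre) == 6
        assert all(po < pr for pr, po in zip(pooled_pre, pooled_post))


class TestPrePostRateTest:
    def test_identical_rates_give_t_zero(self):
        events = list(np.arange(0.5, 100.0, 1.0))
        sessions = [(events, [30.0, 60.0], 100.0)] * 3
        res = pre_post_rate_test(sessions)
        assert res.statistic == pytest.approx(0.0)

    def test_edge_triggers_skipped(self):
        with pytest.raises(ValueError, match="at least 2"):
            pre_post_rate_test([([1.0], [0.2], 10.0), ([1.0], [0.3], 10.0)])

    def test_cohort_suppression_significant(self, ds_cohort):
        sessions = []
        for bundle in ds_cohort:
            triggers = [e.trough_time for e in bundle.result.clean_epileptic
                        if e.event_class in ("interictal_spike", "myoclonic")]
            sessions.append(([r.start for r in bundle.result.ripple_events],
                             triggers, bundle.result.duration))
        res = pre_post_rate_test(sessions)
        assert np.all(res.post < res.pre)
        assert res.pvalue < 0.05
        assert res.statistic > 0


class TestSpwSplit:
    def _session(self, below, above):
        events = []
        for i, v in enumerate(below):
            events.append(_Ev(i, 37.0, spw_power_avg=v))
        for i, v in enumerate(above):
            events.append(_Ev(100 + i, 38.5, spw_power_avg=v))
        return events

    def test_identical_distributions_give_t_zero(self, params):
        sessions = [self._session([2.0, 3.0], [2.0, 3.0]) for _ in range(4)]
        res = spw_amplitude_split_test(sessions, params)
        assert res.statistic == pytest.approx(0.0)

    def test_one_sided_sessions_excluded_with_warning(self, params):
        sessions = [self._session([2.0], [4.0]) for _ in range(2)]
        sessions.append(self._session([2.0], []))
        with pytest.warns(UserWarning, match="one side"):
            res = spw_amplitude_split_test(sessions, params)
        assert res.n == 2

    def test_ds_cohort_amplitude_step_recovered(self, ds_cohort, params):
        res = spw_amplitude_split_test(
            [b.result.ripple_events for b in ds_cohort], params)
        assert np.all(res.post > res.pre)  # above-38 exceeds below-38 everywhere
        assert res.pvalue < 0.05

    def test_wt_sessions_show_no_step(self, wt_trio, params):
        res = spw_amplitude_split_test(
            [b.result.ripple_events for b in wt_trio], params)
        assert res.pvalue > 0.05


class TestSigmoidFit:
    def _logistic(self, x, floor, ceiling, mid, slope):
        return floor + (ceiling - floor) / (1 + np.exp(-(x - mid) / slope))

    def test_noiseless_recovery(self):
        x = np.linspace(36.0, 40.0, 30)
        y = self._logistic(x, 0.1, 0.8, 38.0, 0.3)
        fit = fit_sigmoid_trend(x, y)
        assert fit.converged and not fit.degenerate
        assert fit.floor == pytest.approx(0.1, abs=1e-3)
        assert fit.ceiling == pytest.approx(0.8, abs=1e-3)
        assert fit.midpoint == pytest.approx(38.0, abs=1e-3)

    def test_constant_data_flagged_degenerate(self):
        fit = fit_sigmoid_trend(np.linspace(36, 40, 10), np.full(10, 0.5))
        assert fit.degenerate

    def test_noisy_midpoint_within_tolerance(self):
        rng = np.random.default_rng(18)
        x = np.linspace(36.0, 40.0, 40)
        y = self._logistic(x, 0.1, 0.8, 38.0, 0.3) + rng.normal(0, 0.03, x.size)
        fit = fit_sigmoid_trend(x, y)
        assert fit.converged
        assert fit.midpoint == pytest.approx(38.0, abs=0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid_trend([1, 2, 3], [1, 2, 3])


class TestTrendAndGroupStats:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_trend(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_grand_average_formula(self):
        mean, sem = grand_average([10.0, 20.0, 30.0])
        assert mean == pytest.approx(20.0)
        assert sem == pytest.approx(10.0 / np.sqrt(3))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_combined_interface(self):
        out = trend_and_group_stats(np.arange(5.0), 3 * np.arange(5.0),
                                    [10.0, 20.0, 30.0])
        assert out.r == pytest.approx(1.0)
        assert out.grand_mean == pytest.approx(20.0)
        assert out.n_subjects == 3

    def test_frequency_temperature_correlation_positive_per_subject(
            self, ds_cohort, wt_trio):
        for bundle in ds_cohort + wt_trio:
            events = bundle.result.ripple_events
            r, p = pearson_trend([e.temperature for e in events],
                                 [e.frequency for e in events])
            assert r > 0
            assert p < 0.05
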