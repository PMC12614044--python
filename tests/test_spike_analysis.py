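import numpy as np
import pytest

from ripplelab.core import CellClass, EventTable, SpikeTrain, ValidationError
from ripplelab.spikes import (FiringType, classify_firing_type, correlogram,
                              csb_rate, detect_bursts, detect_spikes,
                              first_spike_differences, fit_rmi,
                              last_spike_before, peth, windowed_rates)
from ripplelab.synth import generate_loosepatch_trace, generate_model_ccg


def _train(times, cls=CellClass.UNKNOWN, uid="u"):
    return SpikeTrain(np.asarray(times, float), uid, cls)


@pytest.fixture(scope="module")
def spike_times():
    rng = np.random.default_rng(11)
    t = np.sort(rng.uniform(0.05, 1.95, 120))
    return t[np.concatenate(([True], np.diff(t) > 0.004))]


class TestDetectSpikes:
    def test_template_spikes_recovered_with_low_jitter(self, spike_times):
        trace = generate_loosepatch_trace(spike_times, 2.0, seed=1)
        det = detect_spikes(trace)
        assert len(det) == spike_times.size
        errs = [np.min(np.abs(det.times - t)) * 1e3 for t in spike_times]
        assert max(errs) <= 0.2

    def test_inverted_polarity_not_detected(self, spike_times):
        trace = generate_loosepatch_trace(spike_times, 2.0, spike_amp=-1.0, seed=1)
        assert len(detect_spikes(trace)) == 0

    def test_doublet_within_dead_time_counted_once(self):
        base = np.arange(0.1, 1.9, 0.02)
        times = np.sort(np.concatenate([base, [1.93, 1.9305]]))
        trace = generate_loosepatch_trace(times, 2.0, seed=2)
        det = detect_spikes(trace)
        in_doublet = np.sum((det.times > 1.925) & (det.times < 1.935))
        assert in_doublet == 1

    def test_flat_trace_rejected(self):
        from ripplelab.core import TimeSeries
        with pytest.raises(ValidationError):
            detect_spikes(TimeSeries(np.zeros(5000), 20000.0))


class TestCorrelogram:
    def test_identical_trains_pile_at_zero_lag(self):
        a = _train(np.arange(0.5, 10.0, 0.1))
        ccg = correlogram(a, a)
        assert ccg.counts[ccg.lags == 0][0] == len(a)

    def test_autocorrelogram_drops_zero_lag_and_is_flat_for_poisson(self, rng):
        rate, dur = 50.0, 200.0
        t = np.sort(rng.uniform(0, dur, int(rate * dur)))
        t = t[np.concatenate(([True], np.diff(t) > 0))]
        acg = correlogram(_train(t), None)
        assert acg.zero_lag_removed and 0.0 not in acg.lags
        expect = rate * t.size * 1e-3  # rate * n * binwidth
        assert np.mean(acg.counts) == pytest.approx(expect, rel=0.05)
        assert np.std(acg.counts) < 0.1 * expect

    def test_ripple_locked_pair_peaks_at_multiples_of_period(self):
        # both cells fire on a 200 Hz clock; lags pile at 0, +/-5, +/-10 ms
        clock = np.arange(1.0, 20.0, 0.005)
        a = _train(clock[::2])
        b = _train(clock[::3])
        ccg = correlogram(a, b, max_lag_ms=12.0)
        hot = set(ccg.lags[ccg.counts > 0])
        assert hot <= {-10.0, -5.0, 0.0, 5.0, 10.0}
        assert ccg.counts[ccg.lags == 0][0] > 0

    def test_mirror_symmetry(self, rng):
        a = _train(np.sort(rng.uniform(0, 30, 400)))
        b = _train(np.sort(rng.uniform(0, 30, 300)))
        ab = correlogram(a, b)
        ba = correlogram(b, a)
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])

    def test_empty_train_rejected(self):
        with pytest.raises(ValidationError):
            correlogram(_train([]))


class TestFitRmi:
    def test_parameters_recovered_from_model_correlogram(self):
        # high-count fixture: modulation ratio 0.5 at 200 Hz, tau 20 ms
        for seed in range(4):
            ccg = generate_model_ccg(50.0, 100.0, 2 * np.pi * 200.0, 0.0,
                                     20.0, 20_000, seed=seed)
            fit = fit_rmi(ccg)
            assert 0.45 <= fit.rmi <= 0.55
            assert abs(fit.freq_hz - 200.0) <= 10.0
            assert abs(fit.tau_ms - 20.0) <= 4.0

    def test_null_correlogram_gives_small_index(self):
        for seed in range(4):
            ccg = generate_model_ccg(0.0, 100.0, 2 * np.pi * 200.0, 0.0,
                                     20.0, 50_000, seed=seed)
            assert fit_rmi(ccg).rmi <= 0.05

    def test_swr_state_modulation_exceeds_ied_state(self, swr_recording,
                                                    ied_recording):
        # synchronized ripple-locked firing vs desynchronized epileptiform
        out = {}
        for name, rec in (("swr", swr_recording), ("ied", ied_recording)):
            pv = [t for t in rec.spikes if t.cell_class is CellClass.PVBC]
            out[name] = fit_rmi(correlogram(pv[0], pv[1])).rmi
        assert out["swr"] > 3 * out["ied"]
        assert out["swr"] > 0.4

    def test_short_correlogram_rejected(self):
        ccg = generate_model_ccg(0.0, 100.0, 2 * np.pi * 200.0, 0.0, 20.0,
                                 5000, seed=0, max_lag_ms=20.0)
        with pytest.raises(ValidationError):
            fit_rmi(ccg)


class TestPeth:
    def test_repeated_pattern_reproduced(self):
        pattern = np.array([0.0024, 0.0053, 0.0112])
        triggers = np.arange(1.0, 21.0)
        spikes = np.sort(np.concatenate([trg + pattern for trg in triggers]))
        h = peth(_train(spikes), triggers, (-20.0, 20.0))
        assert h.n_events == 20
        hot = h.centers_ms[h.counts > 0]
        np.testing.assert_allclose(sorted(hot), [2.5, 5.5, 11.5])  # bin centers
        assert np.all(h.counts[h.counts > 0] == 20)
        assert np.all(h.prob[h.counts > 0] == 1.0)

    def test_empty_train_gives_zero_peth(self):
        h = peth(_train([]), [1.0, 2.0], (-50.0, 50.0))
        assert np.all(h.counts == 0) and np.all(h.prob == 0)

    def test_shift_invariance(self, rng):
        spikes = np.sort(rng.uniform(0, 50, 300))
        triggers = np.arange(5.0, 45.0, 2.0)
        h0 = peth(_train(spikes), triggers, (-50.0, 50.0))
        h1 = peth(_train(spikes + 7.0), triggers + 7.0, (-50.0, 50.0))
        np.testing.assert_array_equal(h0.counts, h1.counts)

    def test_poisson_train_is_flat(self, rng):
        spikes = np.sort(rng.uniform(0, 500, 10_000))
        triggers = np.arange(10.0, 490.0, 5.0)
        h = peth(_train(spikes), triggers, (-50.0, 50.0))
        expect = h.n_events * 20.0 * 1e-3  # rate 20 Hz x 1 ms bins
        assert np.mean(h.counts) == pytest.approx(expect, rel=0.1)
        assert np.max(np.abs(h.counts - expect)) < 6 * np.sqrt(expect)


class TestWindowedRates:
    def test_constant_rate_is_recovered_in_all_windows(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0.0, 1000.0, 10_000))  # 10 Hz Poisson
        onsets = np.arange(5.0, 995.0, 2.0)
        rates = windowed_rates(_train(spikes), onsets)
        for v in rates.values():
            assert v == pytest.approx(10.0, rel=0.1)

    def test_empty_windows_give_zero(self):
        rates = windowed_rates(_train([5.0]), [20.0])
        assert all(v == 0.0 for v in rates.values())


class TestLastSpikeBefore:
    def test_strictly_before_semantics(self):
        tr = _train([1.0, 2.0, 3.0])
        assert last_spike_before(tr, [1.5]) == [1.0]
        assert last_spike_before(tr, [0.5]) == [None]
        assert last_spike_before(tr, [2.0]) == [1.0]  # ties excluded


class TestBursts:
    def test_isi_rule_delimits_bursts(self):
        isis_s = np.array([3, 4, 5, 200, 3, 4]) / 1e3
        spikes = np.concatenate([[0.0], np.cumsum(isis_s)]) + 1.0
        bursts = detect_bursts(_train(spikes), max_isi_ms=15.0, min_spikes=2)
        assert [b.n_spikes for b in bursts] == [4, 3]
        np.testing.assert_allclose(bursts[0].isis_ms, [3, 4, 5])

    def test_long_isis_give_no_bursts(self):
        spikes = np.arange(0.0, 2.0, 0.1)
        assert detect_bursts(_train(spikes)) == []

    def test_min_spikes_threshold(self):
        spikes = np.array([1.0, 1.004])
        assert len(detect_bursts(_train(spikes), min_spikes=2)) == 1
        assert len(detect_bursts(_train(spikes), min_spikes=3)) == 0


@pytest.fixture(scope="module")
def events():
    return EventTable.from_records(
        [{"kind": "IED", "peak_time": float(k), "trigger_time": float(k),
          "onset_time": float(k) - 0.01} for k in range(2, 26, 2)])


class TestClassification:
    def test_theta_above_one_forces_type_one(self, events):
        # a cell bursting before every event is still type I at theta > 1
        onsets = events.onset_times
        spikes = np.sort(np.concatenate(
            [o - 0.1 + np.array([0, 0.004, 0.008]) for o in onsets]))
        tr = _train(spikes)
        assert classify_firing_type(tr, events, [], theta=1.01) is FiringType.TYPE_I
        assert classify_firing_type(tr, events, [], theta=0.2) is FiringType.TYPE_II

    def test_too_few_events_unclassified(self, events):
        few = EventTable(events.df.head(3))
        tr = _train([1.0, 1.004, 1.008])
        assert classify_firing_type(tr, few, []) is FiringType.UNCLASSIFIED

    def test_bursts_inside_fastrip_window_do_not_count(self, events):
        onsets = events.onset_times
        spikes = np.sort(np.concatenate(
            [o - 0.05 + np.array([0, 0.004, 0.008]) for o in onsets]))
        windows = [(o - 0.06, o) for o in onsets]
        got = classify_firing_type(_train(spikes), events, windows, theta=0.2)
        assert got is FiringType.TYPE_I


class TestFirstSpikeDifferences:
    def _events(self, times):
        return EventTable.from_records(
            [{"kind": "IED", "peak_time": float(t), "trigger_time": float(t)}
             for t in times])

    def test_identical_trains_give_zero(self):
        ev_times = np.arange(1.0, 11.0)
        tr = _train(np.sort(np.concatenate([ev_times + 0.002, ev_times + 0.006])))
        d = first_spike_differences(tr, tr, self._events(ev_times))
        assert np.all(d == 0)

    def test_shift_moves_the_mean(self):
        ev_times = np.arange(1.0, 11.0)
        a = _train(ev_times + 0.002)
        b = _train(ev_times + 0.004)  # B fires 2 ms later
        d = first_spike_differences(a, b, self._events(ev_times))
        assert np.mean(d) == pytest.approx(-2.0, abs=1e-9)

    def test_variance_addition_at_large_n(self):
        # independent per-cell onset jitter of 1.65 ms -> difference SD x sqrt(2)
        rng = np.random.default_rng(42)
        ev_times = np.arange(1.0, 701.0)
        a = _train(np.sort(ev_times + 0.24e-3 + 1.65e-3 * rng.standard_normal(700)))
        b = _train(np.sort(ev_times + 0.24e-3 + 1.65e-3 * rng.standard_normal(700)))
        d = first_spike_differences(a, b, self._events(ev_times))
        assert d.size == 700
        assert np.std(d) == pytest.approx(1.65 * np.sqrt(2), rel=0.08)


class TestCsbRate:
    def test_extremes(self):
        burst = [0.0, 0.004, 0.008, 0.013]
        single = [0.0, 0.2, 0.4]
        assert csb_rate([burst] * 5) == 1.0
        assert csb_rate([single] * 5) == 0.0

    def test_fraction_matches_burst_probability(self, rng):
        steps = []
        p = 0.75
        for _ in range(200):
            if rng.random() < p:
                steps.append([0.0, 0.004, 0.008, 0.013])
            else:
                steps.append([0.0, 0.2])
        assert csb_rate(steps) == pytest.approx(p, abs=0.1)

    def test_needs_three_steps(self):
        with pytest.raises(ValidationError):
            csb_rate([[0.0, 0.004, 0.008]])
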