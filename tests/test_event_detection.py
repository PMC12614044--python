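import numpy as np
import pytest

from ripplelab.core import (FASTRIP_POWER_BAND, RIPPLE_BAND, TimeSeries,
                            ValidationError)
from ripplelab.detect import (DetectionError, ONSET_SMOOTH_FC, detect_ied,
                              detect_swr, event_triggered_average,
                              fastrip_onset, power_change, reconcile_events,
                              ripple_trigger_time)
from ripplelab.filters import PowerEnvelope, band_filter, power_envelope
from ripplelab.synth import (IedConfig, SwrConfig, SynthConfig,
                             generate_recording, trough_ref)

FS = 10_000.0


def _match_errors_ms(detected, truth):
    return np.array([np.min(np.abs(detected - t)) * 1e3 for t in truth])


class TestSwrDetection:
    def test_recovers_embedded_events(self, mixed_recording):
        rec = mixed_recording
        merged = reconcile_events(detect_swr(rec.lfp[0]), detect_ied(rec.lfp[0]))
        errs = _match_errors_ms(merged.of_kind("SWR").peak_times,
                                rec.truth.swr_times)
        assert np.all(errs <= 5.0)

    def test_no_false_positives_on_ground_truth(self, mixed_recording):
        rec = mixed_recording
        merged = reconcile_events(detect_swr(rec.lfp[0]), detect_ied(rec.lfp[0]))
        for kind, truth in (("SWR", rec.truth.swr_times),
                            ("IED", rec.truth.ied_times)):
            for t in merged.of_kind(kind).peak_times:
                assert np.min(np.abs(truth - t)) * 1e3 <= 10.0

    def test_subthreshold_event_not_detected(self):
        # one sharp wave above threshold, an amplitude-halved copy below
        rng = np.random.default_rng(2)
        n = int(10 * FS)
        t = np.arange(n) / FS
        x = 0.03 * rng.standard_normal(n)
        x -= 2.0 * np.exp(-(t - 3.0) ** 2 / (2 * 0.018 ** 2))
        x -= 0.25 * np.exp(-(t - 7.0) ** 2 / (2 * 0.018 ** 2))
        ev = detect_swr(TimeSeries(x, FS))
        assert len(ev) == 1
        assert abs(ev.peak_times[0] - 3.0) < 0.005

    def test_flat_signal_raises(self):
        with pytest.raises(DetectionError):
            detect_swr(TimeSeries(np.zeros(int(2 * FS)), FS))

    def test_translation_equivariance(self, swr_recording):
        lfp = swr_recording.lfp[0]
        shifted = TimeSeries(lfp.samples, lfp.fs, t0=lfp.t0 + 12.5)
        ev0 = detect_swr(lfp).peak_times
        ev1 = detect_swr(shifted).peak_times
        np.testing.assert_allclose(ev1, ev0 + 12.5, atol=1e-9)

    def test_sensitivity_monotone_in_snr(self):
        # weaker sharp waves never raise sensitivity
        sens = []
        for amp in (0.3, 0.9, 2.8):
            cfg = SynthConfig(duration=30.0, seed=6, ied=IedConfig(rate=0.0),
                              swr=SwrConfig(sw_amp=amp))
            rec = generate_recording(cfg)
            det = detect_swr(rec.lfp[0]).peak_times
            errs = _match_errors_ms(det, rec.truth.swr_times) if det.size else \
                np.full(rec.truth.swr_times.size, np.inf)
            sens.append(np.mean(errs <= 5.0))
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] == 1.0


class TestRippleTrigger:
    def test_trigger_lands_on_a_ripple_trough(self, swr_recording):
        rec = swr_recording
        f_r = rec.config.swr.ripple_freq
        for tc, ph in zip(rec.truth.swr_times[:8], rec.truth.swr_phases[:8]):
            trig = ripple_trigger_time(rec.lfp[0], tc)
            base = trough_ref(tc, ph, f_r)
            dist = abs(trig - base - round((trig - base) * f_r) / f_r) * 1e3
            assert dist <= 2.5  # within half a ripple cycle of a true trough

    def test_trigger_aligned_average_preserves_ripple_phase(self, swr_recording):
        rec = swr_recording
        lfp = rec.lfp[0]
        bf = band_filter(lfp, RIPPLE_BAND)
        trig = [ripple_trigger_time(lfp, t) for t in rec.truth.swr_times]
        _, avg_t, _ = event_triggered_average(bf, trig, (-0.02, 0.02))
        _, avg_p, _ = event_triggered_average(bf, rec.truth.swr_times, (-0.02, 0.02))

        def ripple_amp(avg):
            tt = np.arange(avg.size) / lfp.fs
            return 2 * abs(np.mean((avg - avg.mean())
                                   * np.exp(-2j * np.pi * 200.0 * tt)))

        assert ripple_amp(avg_t) > 3 * ripple_amp(avg_p)

    def test_peak_on_trough_returns_it(self):
        t = np.arange(int(2 * FS)) / FS
        x = -np.cos(2 * np.pi * 200.0 * (t - 1.0))  # trough exactly at t=1
        trig = ripple_trigger_time(TimeSeries(x, FS), 1.0)
        assert trig == pytest.approx(1.0, abs=1e-4)

    def test_fallback_warns_when_no_trough_in_window(self, swr_recording):
        lfp = swr_recording.lfp[0]
        with pytest.warns(UserWarning):
            trig = ripple_trigger_time(lfp, 5.0, search=1e-4)
        assert trig == 5.0


class TestIedDetection:
    def test_recovers_embedded_events(self, ied_recording):
        rec = ied_recording
        ev = detect_ied(rec.lfp[0])
        errs = _match_errors_ms(ev.peak_times, rec.truth.ied_times)
        assert len(ev) == rec.truth.ied_times.size
        assert np.all(errs <= 5.0)

    def test_swr_only_recording_yields_no_ied(self, swr_recording):
        assert len(detect_ied(swr_recording.lfp[0])) == 0

    def test_refractory_merges_close_events(self):
        # two fast-ripple bursts 100 ms apart with a 200 ms refractory gap
        rng = np.random.default_rng(3)
        n = int(6 * FS)
        x = 0.02 * rng.standard_normal(n)
        t = np.arange(n) / FS
        for tc, amp in ((3.0, 0.5), (3.1, 0.3)):
            x += amp * np.exp(-(t - tc) ** 2 / (2 * 0.004 ** 2)) \
                * np.sin(2 * np.pi * 300.0 * (t - tc))
        ev = detect_ied(TimeSeries(x, FS), k_sd=8.0, refractory=0.2)
        assert len(ev) == 1
        assert abs(ev.peak_times[0] - 3.0) < 0.02  # the larger peak wins


class TestFastripOnset:
    def test_triangular_envelope_closed_form(self):
        # linear rise from 0 over 20 ms: 5% crossing at 5% of the rise
        fs = 1000.0
        v = np.concatenate([np.zeros(100), np.linspace(0, 1, 21),
                            np.linspace(1, 0, 21)[1:], np.zeros(100)])
        env = PowerEnvelope(v, fs, 0.0, FASTRIP_POWER_BAND, 20.0)
        peak = np.argmax(v) / fs
        onset = fastrip_onset(env, peak, frac=0.05)
        assert onset == pytest.approx(0.100 + 0.05 * 0.020, abs=1.5 / fs)

    def test_frac_one_returns_peak(self):
        fs = 1000.0
        v = np.concatenate([np.zeros(100), np.linspace(0, 1, 21),
                            np.linspace(1, 0, 21)[1:], np.zeros(100)])
        env = PowerEnvelope(v, fs, 0.0, FASTRIP_POWER_BAND, 20.0)
        peak = np.argmax(v) / fs
        assert fastrip_onset(env, peak, frac=1.0) == pytest.approx(peak)

    def test_generator_onset_recovered(self, ied_recording):
        rec = ied_recording
        env = power_envelope(rec.lfp[0], FASTRIP_POWER_BAND, ONSET_SMOOTH_FC)
        ev = detect_ied(rec.lfp[0])
        for pk in ev.peak_times:
            j = int(np.argmin(np.abs(rec.truth.ied_times - pk)))
            onset = fastrip_onset(env, pk)
            assert abs(onset - rec.truth.ied_onsets[j]) * 1e3 <= 2.0

    def test_envelope_never_below_threshold_raises(self):
        env = PowerEnvelope(np.full(1000, 5.0), 1000.0, 0.0,
                            FASTRIP_POWER_BAND, 20.0)
        with pytest.raises(DetectionError):
            fastrip_onset(env, 0.5)


class TestEventTriggeredAverage:
    def test_identical_segments_average_to_segment(self):
        fs = 1000.0
        seg = np.sin(2 * np.pi * 10 * np.arange(101) / fs)
        x = np.zeros(int(10 * fs))
        triggers = [2.0, 4.0, 6.0]
        for trg in triggers:
            i = int(trg * fs)
            x[i - 50:i + 51] = seg
        _, avg, n = event_triggered_average(TimeSeries(x, fs), triggers,
                                            (-0.05, 0.05))
        assert n == 3
        np.testing.assert_allclose(avg, seg, atol=1e-12)

    def test_single_trigger_returns_that_segment(self, rng):
        fs = 1000.0
        x = rng.standard_normal(int(4 * fs))
        _, avg, n = event_triggered_average(TimeSeries(x, fs), [2.0], (-0.1, 0.1))
        i = int(2.0 * fs)
        assert n == 1
        np.testing.assert_array_equal(avg, x[i - 100:i + 101])

    def test_noise_shrinks_as_sqrt_n(self, rng):
        fs = 1000.0
        n_ev = 100
        seg = np.sin(2 * np.pi * 20 * np.arange(101) / fs)
        x = rng.standard_normal(int((n_ev + 2) * fs))
        triggers = np.arange(1, n_ev + 1, dtype=float)
        for trg in triggers:
            i = int(trg * fs)
            x[i - 50:i + 51] += seg
        _, avg, _ = event_triggered_average(TimeSeries(x, fs), triggers,
                                            (-0.05, 0.05))
        resid_sd = np.std(avg - seg)
        assert resid_sd == pytest.approx(1.0 / np.sqrt(n_ev), rel=0.35)

    def test_all_triggers_outside_raises(self, rng):
        ts = TimeSeries(rng.standard_normal(1000), 1000.0)
        with pytest.raises(DetectionError):
            event_triggered_average(ts, [50.0], (-0.1, 0.1))


class TestPowerChange:
    def _swr_pair(self, scale):
        cfg = SynthConfig(duration=30.0, seed=9, ied=IedConfig(rate=0.0))
        base = generate_recording(cfg)
        drug_samples = base.lfp[0].samples.copy()
        return base, drug_samples

    def test_identical_conditions_give_zero(self, swr_recording):
        lfp = swr_recording.lfp[0]
        trig = swr_recording.truth.swr_times
        change = power_change(lfp, lfp, trig, trig, RIPPLE_BAND, (-0.05, 0.05))
        assert change == pytest.approx(0.0, abs=1e-9)

    def test_globally_halved_amplitude_gives_minus_fifty(self, swr_recording):
        # envelope 1-homogeneity: scaling the trace scales the AUC
        lfp = swr_recording.lfp[0]
        half = TimeSeries(0.5 * lfp.samples, lfp.fs)
        trig = swr_recording.truth.swr_times
        change = power_change(lfp, half, trig, trig, RIPPLE_BAND, (-0.05, 0.05))
        assert change == pytest.approx(-50.0, abs=0.5)

    def test_too_few_triggers_rejected(self, swr_recording):
        lfp = swr_recording.lfp[0]
        with pytest.raises(ValidationError):
            power_change(lfp, lfp, [1.0], [1.0], RIPPLE_BAND, (-0.05, 0.05))
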