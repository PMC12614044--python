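"""End-to-end validation experiments on synthetic ground truth.

Each function runs one closed-loop experiment — generate data with known
structure, run the analysis, measure recovery — and returns a flat dict of
scalar metrics. They are used by the test suite and by the reproduction
script; every experiment is deterministic given its seed.

Problem sizes (60 s recordings at 10 kHz, 20 fit repetitions per grid cell,
300 coherence surrogates, 10,000 Monte-Carlo burst draws) are the package's
validation defaults and match the conditions the analyses are designed for.
"""

from __future__ import annotations

import numpy as np

from . import detect as det
from . import pseudosync as psy
from . import spikes as spk
from .coherence import (band_window_coherence, coherence_significance,
                        default_freqs, wavelet_coherence, _ar1)
from .core import (BandDef, CellClass, FASTRIP_COH_BAND, FASTRIP_POWER_BAND,
                   MUA_BAND, RIPPLE_BAND, TimeSeries)
from .filters import band_filter, power_envelope, rc_filter
from .pipeline import _decimated, run_pipeline
from .synth import (IedConfig, PcConfig, PvbcConfig, SwrConfig, SynthConfig,
                    generate_drug_condition, generate_model_ccg,
                    generate_recording, generate_template_library)

__all__ = [
    "zero_phase_check", "detection_recovery", "rmi_recovery",
    "wtc_calibration", "coherence_contrast", "pseudosynchrony",
    "classification_check", "drug_contrasts", "pipeline_determinism",
]


def _sub_seeds(seed: int, n: int, salt: int) -> list[int]:
    rng = np.random.default_rng((seed, salt))
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


def zero_phase_check(seed: int = 0) -> dict:
    """Cross-correlation lag between a band-limited signal and its two-way
    RC band-filtered version; zero-phase filtering must peak at lag 0."""
    rng = np.random.default_rng(seed)
    fs = 10_000.0
    t = np.arange(int(fs)) / fs
    x = np.sin(2 * np.pi * 200.0 * t) * np.exp(-(t - 0.5) ** 2 / (2 * 0.05 ** 2))
    x += 0.05 * rng.standard_normal(t.size)
    ts = TimeSeries(x, fs)
    y = band_filter(ts, RIPPLE_BAND).samples
    lags = np.arange(-50, 51)
    xc = [np.dot(x, np.roll(y, k)) for k in lags]
    return {"xcorr_peak_lag_samples": int(lags[int(np.argmax(xc))])}


def detection_recovery(seed: int = 0, duration: float = 60.0) -> dict:
    """Detect SWRs and IEDs in a mixed synthetic recording and score
    sensitivity, false positives, and timing errors against ground truth."""
    cfg = SynthConfig(duration=duration, seed=seed)
    rec = generate_recording(cfg)
    tr, lfp = rec.truth, rec.lfp[0]
    merged = det.reconcile_events(det.detect_swr(lfp), det.detect_ied(lfp))
    sw, ie = merged.of_kind("SWR"), merged.of_kind("IED")

    def errs(det_t, true_t):
        return np.array([np.min(np.abs(det_t - t)) * 1e3 for t in true_t])

    e_swr = errs(sw.peak_times, tr.swr_times)
    e_ied = errs(ie.peak_times, tr.ied_times)
    fp = sum(1 for t in sw.peak_times if np.min(np.abs(tr.swr_times - t)) * 1e3 > 10)
    fp += sum(1 for t in ie.peak_times if np.min(np.abs(tr.ied_times - t)) * 1e3 > 10)
    env = power_envelope(lfp, FASTRIP_POWER_BAND, det.ONSET_SMOOTH_FC)
    e_on = []
    for pk in ie.peak_times:
        j = int(np.argmin(np.abs(tr.ied_times - pk)))
        e_on.append(abs(det.fastrip_onset(env, pk) - tr.ied_onsets[j]) * 1e3)
    return {
        "n_true_swr": int(tr.swr_times.size),
        "n_true_ied": int(tr.ied_times.size),
        "swr_sensitivity_pct": 100.0 * float(np.mean(e_swr <= 5.0)),
        "ied_sensitivity_pct": 100.0 * float(np.mean(e_ied <= 5.0)),
        "false_positives": int(fp),
        "swr_peak_error_ms_max": float(e_swr.max()),
        "ied_peak_error_ms_max": float(e_ied.max()),
        "fastrip_onset_error_ms_max": float(max(e_on)),
    }


def rmi_recovery(seed: int = 0, n_seeds: int = 20, n_null: int = 60,
                 n_counts: int = 5000) -> dict:
    """Ripple-modulation-index parameter recovery on model correlograms.

    Multinomial correlograms are drawn from the Gaussian-windowed sinusoid
    over a grid of modulation ratios and frequencies; the fraction recovered
    within +/-10% (relative) and the null specificity (RMI <= 0.05 on
    modulation-free correlograms) are reported.
    """
    ok = tot = 0
    ss = iter(_sub_seeds(seed, 12 * n_seeds + n_null, salt=3))
    for ab in (0.1, 0.25, 0.5, 1.0):
        for f in (160.0, 200.0, 240.0):
            for _ in range(n_seeds):
                ccg = generate_model_ccg(ab * 100.0, 100.0, 2 * np.pi * f,
                                         0.0, 20.0, n_counts, seed=next(ss))
                fit = spk.fit_rmi(ccg)
                tot += 1
                ok += abs(fit.rmi - ab) <= 0.1 * ab
    null_ok = 0
    for _ in range(n_null):
        ccg = generate_model_ccg(0.0, 100.0, 2 * np.pi * 200.0, 0.0, 20.0,
                                 n_counts, seed=next(ss))
        null_ok += spk.fit_rmi(ccg).rmi <= 0.05
    return {
        "rmi_recovery_rate_pct": 100.0 * ok / tot,
        "rmi_null_rate_pct": 100.0 * null_ok / n_null,
        "n_grid_fits": tot,
        "n_null_fits": n_null,
    }


def wtc_calibration(seed: int = 0, n_surrogates: int = 300,
                    n_test: int = 20, alpha: float = 0.05) -> dict:
    """Self-coherence inside the cone of influence and red-noise
    significance calibration of the wavelet transform coherence."""
    rng = np.random.default_rng(seed)
    fs, n, r = 500.0, 2000, 0.8
    freqs = default_freqs(8.0, 120.0)
    a = TimeSeries(_ar1(rng, r, n), fs)
    cm_self = wavelet_coherence(a, a, freqs)
    min_self = float(cm_self.coh[cm_self.coi_mask()].min())
    base = wavelet_coherence(TimeSeries(_ar1(rng, r, n), fs),
                             TimeSeries(_ar1(rng, r, n), fs), freqs)
    sig = coherence_significance(base, TimeSeries(_ar1(rng, r, n), fs),
                                 TimeSeries(_ar1(rng, r, n), fs),
                                 n_surrogates=n_surrogates, alpha=alpha,
                                 seed=int(rng.integers(2**31 - 1)))
    fracs = []
    for _ in range(n_test):
        m = wavelet_coherence(TimeSeries(_ar1(rng, r, n), fs),
                              TimeSeries(_ar1(rng, r, n), fs), freqs)
        mask = (m.coh > sig.thresholds[:, None]) & m.coi_mask()
        fracs.append(mask.sum() / m.coi_mask().sum())
    return {
        "self_coherence_min_in_coi": min_self,
        "flagged_fraction_pct": 100.0 * float(np.mean(fracs)),
        "n_surrogates": n_surrogates,
    }


def coherence_contrast(seed: int = 0, duration: float = 60.0) -> dict:
    """Band/window coherence of a synthetic electrode pair: shared-phase
    ripples during SWRs (150-250 Hz, +/-25 ms) vs per-electrode-independent
    fast-ripples during IEDs (250-500 Hz, +/-50 ms)."""
    s1, s2 = _sub_seeds(seed, 2, salt=5)
    freqs = default_freqs(100.0, 500.0)
    cfg = SynthConfig(duration=duration, seed=s1, n_electrodes=2,
                      ied=IedConfig(rate=0.0))
    rec = generate_recording(cfg)
    cm = wavelet_coherence(_decimated(rec.lfp[0], 2000.0),
                           _decimated(rec.lfp[1], 2000.0), freqs)
    swr_coh = band_window_coherence(cm, det.detect_swr(rec.lfp[0]),
                                    RIPPLE_BAND, 0.025)
    cfg2 = SynthConfig(duration=duration, seed=s2, n_electrodes=2,
                       swr=SwrConfig(rate=0.0))
    rec2 = generate_recording(cfg2)
    cm2 = wavelet_coherence(_decimated(rec2.lfp[0], 2000.0),
                            _decimated(rec2.lfp[1], 2000.0), freqs)
    ied_coh = band_window_coherence(cm2, det.detect_ied(rec2.lfp[0]),
                                    FASTRIP_COH_BAND, 0.050)
    return {
        "swr_band_window_coherence": float(np.mean(swr_coh)),
        "ied_band_window_coherence": float(np.mean(ied_coh)),
        "coherence_contrast": float(np.mean(swr_coh) - np.mean(ied_coh)),
        "n_swr": int(swr_coh.size), "n_ied": int(ied_coh.size),
    }


def pseudosynchrony(seed: int = 0, n_reps: int = 10_000) -> dict:
    """Monte-Carlo pseudosynchrony: periodicity of the population PETH of
    stereotyped bursts at the empirical onset jitter, its ISI-shuffled
    control, and the jitter monotonicity curve (5-run averages)."""
    ss = _sub_seeds(seed, 4, salt=7)
    lib = generate_template_library(seed=ss[0])
    ons = psy.OnsetDistribution(mean_ms=0.24, sd_ms=1.65)
    res = psy.simulate_population_peth(lib, ons, n_reps, 0.0, seed=ss[1])
    sc = psy.periodicity_score(res.counts, res.bin_ms)
    res_sh = psy.simulate_population_peth(psy.shuffle_intraburst(lib, ss[2]),
                                          ons, n_reps, 0.0, seed=ss[1])
    sc_sh = psy.periodicity_score(res_sh.counts, res_sh.bin_ms)
    curve = []
    run_seeds = _sub_seeds(seed, 5, salt=11)
    for sd in (1e-9, 0.5, 1.65, 5.0, 20.0):
        deps = [psy.periodicity_score(
                    psy.simulate_population_peth(
                        lib, psy.OnsetDistribution(mean_ms=0.24, sd_ms=sd),
                        n_reps, 0.0, seed=s).counts)["modulation_depth"]
                for s in run_seeds]
        curve.append(float(np.mean(deps)))
    return {
        "periodicity_peak_freq_hz": sc["peak_freq"],
        "modulation_depth": sc["modulation_depth"],
        "modulation_depth_shuffled": sc_sh["modulation_depth"],
        "depth_ratio_intact_vs_shuffled": sc["modulation_depth"] / sc_sh["modulation_depth"],
        "jitter_curve_monotone": float(all(curve[i] >= curve[i + 1]
                                           for i in range(len(curve) - 1))),
        "n_reps": n_reps,
    }


def classification_check(seed: int = 0, duration: float = 240.0,
                         n_pc1: int = 20, n_pc2: int = 10) -> dict:
    """Firing-type classification of synthetic type-I/type-II pyramidal
    cells against generator labels, plus the type-II windowed-rate
    ordering (Pre-II > Pre-I, Post < Pre-II)."""
    cfg = SynthConfig(duration=duration, seed=seed, swr=SwrConfig(rate=0.0),
                      pc=PcConfig(n_pc1=n_pc1, n_pc2=n_pc2))
    rec = generate_recording(cfg)
    lfp = rec.lfp[0]
    ev = det.annotate_fastrip_onsets(lfp, det.detect_ied(lfp))
    env = power_envelope(lfp, FASTRIP_POWER_BAND, det.ONSET_SMOOTH_FC)
    frwins = [det.fastrip_window(env, pk) for pk in ev.peak_times]
    n_ok = n_cells = 0
    order_ok = 0
    n_pc2_seen = 0
    for tr in rec.spikes:
        if tr.cell_class not in (CellClass.PC_I, CellClass.PC_II):
            continue
        got = spk.classify_firing_type(tr, ev, frwins)
        want = (spk.FiringType.TYPE_I if tr.cell_class is CellClass.PC_I
                else spk.FiringType.TYPE_II)
        n_cells += 1
        n_ok += got == want
        if tr.cell_class is CellClass.PC_II:
            n_pc2_seen += 1
            r = spk.windowed_rates(tr, ev.onset_times)
            order_ok += (r["pre2"] > r["pre1"]) and (r["post"] < r["pre2"])
    return {
        "classification_accuracy_pct": 100.0 * n_ok / n_cells,
        "type2_rate_ordering_pct": 100.0 * order_ok / max(n_pc2_seen, 1),
        "n_cells": n_cells, "n_ied": len(ev),
    }


def drug_contrasts(seed: int = 0, duration: float = 60.0) -> dict:
    """Directions of the synthetic drug effects: GABA-A block removes
    ripple-band power but not MUA; Na-channel block reduces both fast-ripple
    and MUA power; burst slowing lowers the fast-ripple periodicity
    frequency."""
    s1, s2, s3 = _sub_seeds(seed, 3, salt=13)
    win = (-0.05, 0.05)
    cfg = SynthConfig(duration=duration, seed=s1, ied=IedConfig(rate=0.0))
    base, drug = generate_drug_condition(cfg, "gabazine")
    tb = det.detect_swr(base.lfp[0]).peak_times
    td = det.detect_swr(drug.lfp[0]).peak_times
    gz_rip = det.power_change(base.lfp[0], drug.lfp[0], tb, td, RIPPLE_BAND, win)
    gz_mua = det.power_change(base.lfp[0], drug.lfp[0], tb, td, MUA_BAND, win)
    cfg2 = SynthConfig(duration=duration, seed=s2, swr=SwrConfig(rate=0.0))
    base2, drug2 = generate_drug_condition(cfg2, "ttx")
    tb2 = det.detect_ied(base2.lfp[0]).peak_times
    td2 = det.detect_ied(drug2.lfp[0]).peak_times
    ttx_fr = det.power_change(base2.lfp[0], drug2.lfp[0], tb2, td2,
                              BandDef("fastrip", 200.0, 500.0), win)
    ttx_mua = det.power_change(base2.lfp[0], drug2.lfp[0], tb2, td2, MUA_BAND, win)
    # riluzole slows the stereotyped bursts; the emergent periodicity slows
    ons = psy.OnsetDistribution(mean_ms=0.24, sd_ms=1.65)
    lib = generate_template_library(seed=s3)
    lib_slow = generate_template_library(seed=s3, isi0_ms=3.6 * 1.6)
    f0 = psy.periodicity_score(psy.simulate_population_peth(
        lib, ons, 10_000, 0.0, seed=s3).counts, band=(100.0, 350.0))["peak_freq"]
    f1 = psy.periodicity_score(psy.simulate_population_peth(
        lib_slow, ons, 10_000, 0.0, seed=s3).counts, band=(100.0, 350.0))["peak_freq"]
    return {
        "gabazine_ripple_change_pct": gz_rip,
        "gabazine_mua_change_pct": gz_mua,
        "ttx_fastrip_change_pct": ttx_fr,
        "ttx_mua_change_pct": ttx_mua,
        "riluzole_peak_freq_baseline_hz": f0,
        "riluzole_peak_freq_drug_hz": f1,
    }


def pipeline_determinism(seed: int = 0, outdir="scratch/_pipe") -> dict:
    """Two identical pipeline runs must produce byte-identical summaries."""
    from pathlib import Path
    out1, out2 = Path(outdir) / "a", Path(outdir) / "b"
    run_pipeline(seed=seed, outdir=out1)
    run_pipeline(seed=seed, outdir=out2)
    b1 = (out1 / "summary.json").read_bytes()
    b2 = (out2 / "summary.json").read_bytes()
    return {"summaries_identical": float(b1 == b2)}
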