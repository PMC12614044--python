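"""Seeded generator of paired LFP recordings and loose-patch spike trains
with the statistical structure the analysis assumes, plus ground truth for
every pipeline stage.

The generator's core design commitment mirrors the two proposed generating
mechanisms: the SWR ripple is an injected, phase-shared 150-250 Hz
oscillation (standing in for rhythmic perisomatic inhibition), whereas the
fast-ripple of an IED is *not* injected — it emerges from summing the
extracellular waveforms of pseudosynchronous stereotyped pyramidal-cell
bursts whose onsets jitter by ~0.24 +/- 1.65 ms across cells. Basket cells
(PVBCs) are ripple-locked during SWRs and ramp up then fall silent
(depolarization block) around IEDs; type-I pyramidal cells burst only inside
fast-ripple windows; type-II cells additionally burst before events with
ramping probability and are refractory afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .core import CellClass, EventTable, SpikeTrain, TimeSeries, ValidationError
from .spikes import Correlogram, rmi_model

__all__ = [
    "SwrConfig", "IedConfig", "PvbcConfig", "PcConfig", "NoiseConfig",
    "SynthConfig", "GroundTruth", "SynthRecording", "DrugScales",
    "generate_recording", "generate_model_ccg", "generate_drug_condition",
    "generate_template_library", "generate_loosepatch_trace",
]


@dataclass
class SwrConfig:
    rate: float = 20.0 / 60.0       # events/s
    sw_amp: float = 2.8             # sharp-wave amplitude (mV), negative deflection
    sw_sigma: float = 0.018         # sharp-wave Gaussian SD (s)
    ripple_freq: float = 200.0      # Hz
    ripple_amp: float = 0.04        # mV
    ripple_cycles: float = 20.0     # sets the ripple envelope SD
    shared_phase: bool = True       # same ripple phase on both electrodes
    mua_spikes_per_event: float = 25.0
    mua_amp: float = 0.01           # mV per unit spike

    @property
    def ripple_sigma(self) -> float:
        return self.ripple_cycles / (4.0 * self.ripple_freq)


@dataclass
class IedConfig:
    rate: float = 10.0 / 60.0
    slow_amp: float = 1.0           # mV
    slow_sigma_rise: float = 0.008  # s
    slow_sigma_decay: float = 0.035
    slow_decay_shift: float = 0.020
    n_cells: int = 80               # bursting cells summed into the LFP
    n_spikes: int = 5               # spikes per stereotyped burst
    isi0_ms: float = 3.6            # first intraburst ISI
    isi_growth: float = 1.3         # multiplicative ISI lengthening
    isi_jitter: float = 0.1         # fractional per-ISI noise
    burst_scale_sd: float = 0.05    # lognormal per-burst tempo factor
    onset_jitter_mean_ms: float = 0.24
    onset_jitter_sd_ms: float = 1.65
    spike_amp: float = 1.0          # mV, first spike of a burst
    amp_decrement: float = 0.65     # per-spike amplitude decay within a burst
    per_electrode_independent: bool = True


@dataclass
class PvbcConfig:
    n_units: int = 2
    baseline_rate: float = 8.0      # Hz
    swr_lock_prob: float = 0.8      # spike probability per ripple trough
    swr_lock_jitter_ms: float = 0.4
    ramp_rate_max: float = 40.0     # Hz at the end of the pre-IED ramp
    ramp_rate_min: float = 5.0
    block_span: float = 0.100       # silence after fast-ripple onset (s)


@dataclass
class PcConfig:
    n_pc1: int = 2
    n_pc2: int = 1
    participation: float = 0.9      # probability of bursting in an IED
    baseline_rate: float = 0.2      # sparse single spikes (Hz)
    pre1_burst_prob: float = 0.15   # type II: burst probability in Pre-I
    pre2_burst_prob: float = 0.5    # type II: burst probability in Pre-II
    post_refractory: float = 0.300  # type II silence after the event (s)


@dataclass
class NoiseConfig:
    pink_sd: float = 0.05           # mV, 1/f component
    white_sd: float = 0.03          # mV
    f_min: float = 1.0              # 1/f spectrum flattens below this
    f_corner: float = 150.0         # power steepens to 1/f^2 above this


@dataclass
class SynthConfig:
    duration: float = 60.0
    fs: float = 10_000.0
    n_electrodes: int = 1
    seed: int = 0
    swr: SwrConfig = field(default_factory=SwrConfig)
    ied: IedConfig = field(default_factory=IedConfig)
    pvbc: PvbcConfig = field(default_factory=PvbcConfig)
    pc: PcConfig = field(default_factory=PcConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def validate(self) -> None:
        if self.swr.rate < 0 or self.ied.rate < 0:
            raise ValidationError("event rates must be >= 0")
        if self.ied.onset_jitter_sd_ms <= 0:
            raise ValidationError("onset jitter SD must be > 0")
        if self.n_electrodes not in (1, 2):
            raise ValidationError("n_electrodes must be 1 or 2")
        f_max = max(self.swr.ripple_freq, 1e3 / self.ied.isi0_ms)
        if self.fs < 4 * f_max:
            raise ValidationError(
                f"fs must be at least 4x the highest generated frequency ({f_max} Hz)")


@dataclass
class DrugScales:
    """Multiplicative component scales applied by the drug conditions."""

    ripple: float = 1.0
    mua: float = 1.0
    burst_amp: float = 1.0
    slow: float = 1.0
    isi_scale: float = 1.0
    n_spikes_delta: int = 0


_DRUG_PRESETS = {
    # focal Na-channel block: spike-derived LFP attenuated, inhibition-driven
    # ripple only mildly reduced
    "ttx": DrugScales(ripple=0.75, mua=0.35, burst_amp=0.35, slow=0.8),
    # GABA-A block: the inhibition-generated ripple disappears, spiking stays
    "gabazine": DrugScales(ripple=0.0),
    # state-dependent Na block: bursts become slower and shorter
    "riluzole": DrugScales(isi_scale=1.6, n_spikes_delta=-1),
}


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    swr_times: np.ndarray                  # sharp-wave centers (s)
    swr_phases: np.ndarray                 # ripple phase per event (rad)
    swr_trough_times: np.ndarray           # ripple trough nearest each center
    ied_times: np.ndarray                  # population spike mass centers (s)
    ied_onsets: np.ndarray                 # first population spike per event (s)
    fastrip_windows: list[tuple[float, float]]
    cell_classes: dict[str, CellClass]
    burst_onsets: dict[str, list[float]]   # per loose-patch cell
    drug: str | None = None

    def events(self) -> EventTable:
        rec = [{"kind": "SWR", "peak_time": t, "trigger_time": tt,
                "onset_time": np.nan}
               for t, tt in zip(self.swr_times, self.swr_trough_times)]
        rec += [{"kind": "IED", "peak_time": t, "trigger_time": t,
                 "onset_time": o}
                for t, o in zip(self.ied_times, self.ied_onsets)]
        return EventTable.from_records(rec)


@dataclass
class SynthRecording:
    lfp: list[TimeSeries]
    spikes: list[SpikeTrain]
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# helpers

def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float,
                f_min: float, f_corner: float = 150.0) -> np.ndarray:
    """1/f power below ``f_corner``, steepening to 1/f^2 above it — the
    usual shape of extracellular background spectra."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    fc = np.maximum(f, f_min)
    amp = 1.0 / np.sqrt(fc)
    hi = fc > f_corner
    amp[hi] = np.sqrt(f_corner) / fc[hi]
    spec *= amp
    x = np.fft.irfft(spec, n)
    return x * (sd / np.std(x))


def _draw_event_times(rng: np.random.Generator, rate: float, duration: float,
                      margin: float, min_sep: float,
                      avoid: np.ndarray | None = None,
                      avoid_sep: float = 0.5) -> np.ndarray:
    """Poisson number of event times, uniformly placed with a minimum
    separation (and a keep-out zone around ``avoid`` times)."""
    n = rng.poisson(rate * duration)
    times: list[float] = []
    for _ in range(n):
        for _attempt in range(200):
            t = rng.uniform(margin, duration - margin)
            if times and min(abs(t - u) for u in times) < min_sep:
                continue
            if avoid is not None and avoid.size and np.min(np.abs(avoid - t)) < avoid_sep:
                continue
            times.append(t)
            break
    return np.sort(np.asarray(times))


def _spike_kernel(fs: float) -> np.ndarray:
    """Biphasic extracellular waveform of a bursting pyramidal cell
    (~1.5 ms, unit peak, mV); broad enough to carry 200-500 Hz energy."""
    n = max(int(round(2.0e-3 * fs)), 7)
    t = (np.arange(n) - n // 2) / fs * 1e3  # ms
    k = np.exp(-t ** 2 / (2 * 0.2 ** 2)) - 0.6 * np.exp(-(t - 0.45) ** 2 / (2 * 0.3 ** 2))
    return k


def _mua_kernel(fs: float) -> np.ndarray:
    """Narrow biphasic unit waveform (~0.6 ms) whose energy sits above
    500 Hz — the multi-unit component of SWRs."""
    n = max(int(round(1.0e-3 * fs)), 5)
    t = (np.arange(n) - n // 2) / fs * 1e3
    k = np.exp(-t ** 2 / (2 * 0.08 ** 2)) - 0.6 * np.exp(-(t - 0.18) ** 2 / (2 * 0.12 ** 2))
    return k


def _add_gaussian(x: np.ndarray, fs: float, center: float, sigma: float,
                  amp: float) -> None:
    i0 = max(int((center - 5 * sigma) * fs), 0)
    i1 = min(int((center + 5 * sigma) * fs) + 1, x.size)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    x[i0:i1] += amp * np.exp(-(t - center) ** 2 / (2 * sigma ** 2))


def _latent_event_marks(events: list, fs: float, kernel: np.ndarray,
                        frac: float = 0.05, band=(200.0, 500.0),
                        smooth_peak: float = 20.0,
                        smooth_onset: float = 150.0) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (onset, peak) marks of each fast-ripple event.

    Defined by applying the analysis convention — fast-ripple band power
    envelope peak, and the latest upward crossing of ``frac`` of the
    event-local envelope maximum — to the *noise-free* burst component of
    the LFP. The marks are therefore what an ideal detector operating on a
    clean recording would report; detection errors measured against them
    isolate the effect of noise and event overlap.
    """
    from .filters import _rc_apply
    onsets, peaks = [], []
    pad = 0.15
    for spikes, amps in events:
        t0 = spikes.min() - pad
        m = int(round((spikes.max() + pad - t0) * fs))
        delta = np.zeros(m)
        idx = np.round((spikes - t0) * fs).astype(int)
        np.add.at(delta, idx[(idx >= 0) & (idx < m)],
                  amps[(idx >= 0) & (idx < m)])
        clean = fftconvolve(delta, kernel, mode="same")
        bp = _rc_apply(clean, fs, "high", band[0], True)
        bp = _rc_apply(bp, fs, "low", band[1], True)
        rect = np.abs(bp)
        env_pk = _rc_apply(rect, fs, "low", smooth_peak, True)
        env_on = _rc_apply(rect, fs, "low", smooth_onset, True)
        i_pk = int(np.argmax(env_pk))
        peaks.append(t0 + i_pk / fs)
        i_on_pk = int(np.argmax(env_on))
        thr = frac * env_on[i_on_pk]
        below = np.flatnonzero(env_on[:i_on_pk + 1] < thr)
        if below.size:
            i0 = int(below[-1])
            v0, v1 = env_on[i0], env_on[min(i0 + 1, m - 1)]
            t = t0 + i0 / fs
            if v1 > v0:
                t += (thr - v0) / (v1 - v0) / fs
            onsets.append(float(t))
        else:
            onsets.append(float(spikes.min()))
    return np.asarray(onsets), np.asarray(peaks)


def _thin_close(times: np.ndarray, min_isi: float = 1.5e-3) -> np.ndarray:
    times = np.sort(times)
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= min_isi:
            keep.append(t)
            last = t
    return np.asarray(keep)


def _poisson_times(rng: np.random.Generator, rate: float, duration: float
                   ) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def _burst_isis(rng: np.random.Generator, ied: IedConfig,
                scales: DrugScales) -> np.ndarray:
    n_isi = max(ied.n_spikes - 1 + scales.n_spikes_delta, 1)
    base = ied.isi0_ms * ied.isi_growth ** np.arange(ied.n_spikes - 1)
    tempo = np.exp(ied.burst_scale_sd * rng.standard_normal())
    noisy = base * tempo * (1.0 + ied.isi_jitter * rng.standard_normal(ied.n_spikes - 1))
    return np.maximum(noisy[:n_isi], 0.5) * scales.isi_scale


def generate_template_library(n_sequences: int = 300, isi0_ms: float = 3.6,
                              isi_growth: float = 1.3, isi_jitter: float = 0.1,
                              burst_scale_sd: float = 0.05, n_spikes: int = 5,
                              cell_class: CellClass = CellClass.PC_I,
                              unit_id: str | None = None,
                              seed: int | None = None):
    """Stereotyped intraburst ISI library drawn from the default burst
    template — the controlled fixture for the pseudosynchrony Monte Carlo."""
    from .pseudosync import BurstLibrary
    rng = np.random.default_rng(seed)
    base = isi0_ms * isi_growth ** np.arange(n_spikes - 1)
    seqs = [np.maximum(base * np.exp(burst_scale_sd * rng.standard_normal())
                       * (1.0 + isi_jitter * rng.standard_normal(n_spikes - 1)), 1.0)
            for _ in range(n_sequences)]
    uid = unit_id or f"template_{cell_class.value}"
    return BurstLibrary({uid: seqs}, {uid: cell_class})


# ---------------------------------------------------------------------------
# generator

def generate_recording(cfg: SynthConfig,
                       scales: DrugScales | None = None,
                       drug: str | None = None) -> SynthRecording:
    """Generate LFP channel(s), loose-patch spike trains and ground truth.

    ``scales`` applies drug-condition component scaling without perturbing
    the random draw sequence, so a scaled run shares its event schedule and
    spike draws with the unscaled run of the same config.
    """
    cfg.validate()
    scales = scales or DrugScales()
    rng = np.random.default_rng(cfg.seed)
    fs, dur = cfg.fs, cfg.duration
    n = int(round(dur * fs))
    tvec = np.arange(n) / fs

    # --- event schedules (shared across electrodes) ---
    swr_t = _draw_event_times(rng, cfg.swr.rate, dur, margin=0.5, min_sep=0.4)
    ied_t0 = _draw_event_times(rng, cfg.ied.rate, dur, margin=0.8, min_sep=1.0,
                               avoid=swr_t, avoid_sep=0.5)
    swr_phase = rng.uniform(0, 2 * np.pi, swr_t.size)

    # ripple trough nearest each sharp-wave center: cos(2*pi*f*(t-tc)+phi)=-1
    f_r = cfg.swr.ripple_freq
    trough = np.empty_like(swr_t)
    for i, (tc, ph) in enumerate(zip(swr_t, swr_phase)):
        k = np.round((ph - np.pi) / (2 * np.pi) + 0 * tc)
        cand = tc + (np.pi - ph + 2 * np.pi * (k + np.array([-1, 0, 1]))) / (2 * np.pi * f_r)
        trough[i] = cand[np.argmin(np.abs(cand - tc))]

    # --- per-event population bursts (per electrode when independent) ---
    n_pools = cfg.n_electrodes if (cfg.ied.per_electrode_independent
                                   and cfg.n_electrodes == 2) else 1
    pools: list[list[tuple[np.ndarray, np.ndarray]]] = []  # [pool][event] -> (times, amps)
    for _e in range(n_pools):
        per_event = []
        for T in ied_t0:
            spikes = []
            for _c in range(cfg.ied.n_cells):
                onset = T + (cfg.ied.onset_jitter_mean_ms
                             + cfg.ied.onset_jitter_sd_ms * rng.standard_normal()) / 1e3
                isis = _burst_isis(rng, cfg.ied, scales)
                spikes.append(onset + np.concatenate(([0.0], np.cumsum(isis) / 1e3)))
            t_ev = np.concatenate(spikes)
            # complex spike bursts decrement: amplitude decays within a burst
            dec = np.concatenate([cfg.ied.amp_decrement ** np.arange(len(s_))
                                  for s_ in spikes])
            a_ev = cfg.ied.spike_amp * dec * rng.lognormal(0.0, 0.3, t_ev.size)
            order = np.argsort(t_ev)
            per_event.append((t_ev[order], a_ev[order]))
        pools.append(per_event)

    ied_onset, ied_peak = (_latent_event_marks(pools[0], fs, _spike_kernel(fs))
                           if ied_t0.size else (np.empty(0), np.empty(0)))
    frwin = [(float(ev[0] - 1e-3), float(ev[-1] + 2e-3)) for ev, _a in pools[0]]

    # --- LFP channels ---
    kernel = _spike_kernel(fs)
    lfp = []
    for e in range(cfg.n_electrodes):
        x = (_pink_noise(rng, n, fs, cfg.noise.pink_sd, cfg.noise.f_min,
                         cfg.noise.f_corner)
             + cfg.noise.white_sd * rng.standard_normal(n))
        # SWR: sharp wave + amplitude-modulated ripple (+ MUA cluster)
        for tc, ph in zip(swr_t, swr_phase):
            _add_gaussian(x, fs, tc, cfg.swr.sw_sigma, -cfg.swr.sw_amp)
            ph_e = ph if (cfg.swr.shared_phase or e == 0) else rng.uniform(0, 2 * np.pi)
            sig_r = cfg.swr.ripple_sigma
            i0 = max(int((tc - 5 * sig_r) * fs), 0)
            i1 = min(int((tc + 5 * sig_r) * fs) + 1, n)
            tt = tvec[i0:i1]
            x[i0:i1] += (scales.ripple * cfg.swr.ripple_amp
                         * np.exp(-(tt - tc) ** 2 / (2 * sig_r ** 2))
                         * np.cos(2 * np.pi * f_r * (tt - tc) + ph_e))
        mua_delta = np.zeros(n)
        for tc in swr_t:
            n_sp = rng.poisson(cfg.swr.mua_spikes_per_event)
            t_sp = rng.normal(tc, 0.8 * cfg.swr.sw_sigma, n_sp)
            idx = np.round(t_sp * fs).astype(int)
            idx = idx[(idx >= 0) & (idx < n)]
            amps = cfg.swr.mua_amp * rng.lognormal(0.0, 0.3, idx.size)
            np.add.at(mua_delta, idx, amps)
        if swr_t.size:
            x += scales.mua * fftconvolve(mua_delta, _mua_kernel(fs), mode="same")
        # IED: shared slow deflection + pseudosynchronous burst waveforms
        burst_delta = np.zeros(n)
        pool = pools[min(e, n_pools - 1)]
        for T, (ev_spikes, ev_amps) in zip(ied_t0, pool):
            c_slow = T + 0.008
            _add_gaussian(x, fs, c_slow, cfg.ied.slow_sigma_rise,
                          scales.slow * cfg.ied.slow_amp * 0.6)
            _add_gaussian(x, fs, c_slow + cfg.ied.slow_decay_shift,
                          cfg.ied.slow_sigma_decay,
                          scales.slow * cfg.ied.slow_amp * 0.5)
            idx = np.round(ev_spikes * fs).astype(int)
            keep = (idx >= 0) & (idx < n)
            np.add.at(burst_delta, idx[keep], ev_amps[keep])
        if ied_t0.size:
            x += scales.burst_amp * fftconvolve(burst_delta, kernel, mode="same")
        lfp.append(TimeSeries(x, fs, 0.0, f"ch{e}"))

    # --- loose-patch spike trains ---
    trains: list[SpikeTrain] = []
    classes: dict[str, CellClass] = {}
    burst_onsets: dict[str, list[float]] = {}

    for u in range(cfg.pvbc.n_units):
        uid = f"pvbc{u}"
        t_base = _poisson_times(rng, cfg.pvbc.baseline_rate, dur)
        locked = []
        for tc, ph in zip(swr_t, swr_phase):
            # spikes at shared ripple troughs -> pairwise 200 Hz synchrony
            sig_r = cfg.swr.ripple_sigma
            k0 = math.floor((tc - 2.5 * sig_r - trough_ref(tc, ph, f_r)) * f_r)
            k1 = math.ceil((tc + 2.5 * sig_r - trough_ref(tc, ph, f_r)) * f_r)
            for k in range(k0, k1 + 1):
                t_k = trough_ref(tc, ph, f_r) + k / f_r
                if abs(t_k - tc) <= 2.5 * sig_r and rng.random() < cfg.pvbc.swr_lock_prob:
                    locked.append(t_k + rng.normal(0, cfg.pvbc.swr_lock_jitter_ms / 1e3))
        ramp = []
        for T in ied_onset:
            ramp.extend(_ramp_spikes(rng, T, cfg.pvbc.ramp_rate_min,
                                     cfg.pvbc.ramp_rate_max))
        t_all = np.concatenate([t_base, np.asarray(locked), np.asarray(ramp)])
        # depolarization block: hard silence from just before the fast-ripple
        for (w0, _w1), T in zip(frwin, ied_onset):
            t_all = t_all[(t_all < w0 - 0.002) | (t_all > T + cfg.pvbc.block_span)]
        t_all = _thin_close(t_all[(t_all >= 0) & (t_all < dur)])
        trains.append(SpikeTrain(t_all, uid, CellClass.PVBC))
        classes[uid] = CellClass.PVBC
        burst_onsets[uid] = []

    for kind, count in (("pc1", cfg.pc.n_pc1), ("pc2", cfg.pc.n_pc2)):
        cls = CellClass.PC_I if kind == "pc1" else CellClass.PC_II
        for u in range(count):
            uid = f"{kind}_{u}"
            t_base = _thin_close(
                _poisson_times(rng, cfg.pc.baseline_rate, dur), 0.1)
            spikes = [t_base]
            onsets_u: list[float] = []
            for T, (w0, w1) in zip(ied_onset, frwin):
                if rng.random() < cfg.pc.participation:
                    onset = T + (cfg.ied.onset_jitter_mean_ms
                                 + cfg.ied.onset_jitter_sd_ms
                                 * rng.standard_normal()) / 1e3
                    isis = _burst_isis(rng, cfg.ied, scales)
                    spikes.append(onset + np.concatenate(([0.0], np.cumsum(isis) / 1e3)))
                    onsets_u.append(float(onset))
                if cls is CellClass.PC_II:
                    for prob, lo, hi in ((cfg.pc.pre1_burst_prob, -0.29, -0.16),
                                         (cfg.pc.pre2_burst_prob, -0.14, -0.03)):
                        if rng.random() < prob:
                            t_b = T + rng.uniform(lo, hi)
                            isis = _burst_isis(rng, cfg.ied, scales)
                            spikes.append(t_b + np.concatenate(([0.0], np.cumsum(isis) / 1e3)))
                            onsets_u.append(float(t_b))
            t_all = np.concatenate(spikes)
            if cls is CellClass.PC_II:
                for T, (w0, w1) in zip(ied_onset, frwin):
                    t_all = t_all[(t_all < w1) | (t_all > T + cfg.pc.post_refractory)]
            else:
                # type I: baseline singles may not intrude into the pre-event span
                for T in ied_onset:
                    in_pre = (t_all >= T - 0.3) & (t_all < T - 0.005)
                    keep = ~in_pre
                    for w0, w1 in frwin:
                        keep |= (t_all >= w0) & (t_all <= w1)
                    t_all = t_all[keep]
            t_all = _thin_close(t_all[(t_all >= 0) & (t_all < dur)], 1e-3)
            trains.append(SpikeTrain(t_all, uid, cls))
            classes[uid] = cls
            burst_onsets[uid] = onsets_u

    truth = GroundTruth(swr_t, swr_phase, trough, ied_peak, ied_onset, frwin,
                        classes, burst_onsets, drug)
    return SynthRecording(lfp, trains, truth, cfg)


def trough_ref(tc: float, phase: float, f_r: float) -> float:
    """Reference ripple trough time for an event (cos(... ) = -1 branch
    nearest the sharp-wave center)."""
    base = tc + (np.pi - phase) / (2 * np.pi * f_r)
    k = round((tc - base) * f_r)
    return base + k / f_r


def _ramp_spikes(rng: np.random.Generator, onset: float, r0: float,
                 r1: float) -> list[float]:
    """Inhomogeneous Poisson spikes with linearly ramping rate in the
    (-300 ms, -10 ms) window before an IED onset (thinning)."""
    w0, w1 = onset - 0.300, onset - 0.010
    n_cand = rng.poisson(r1 * (w1 - w0))
    t_cand = rng.uniform(w0, w1, n_cand)
    frac = (t_cand - w0) / (w1 - w0)
    rate = r0 + (r1 - r0) * frac
    return list(t_cand[rng.random(n_cand) < rate / r1])


# ---------------------------------------------------------------------------

def generate_loosepatch_trace(spike_times, duration: float, fs: float = 20_000.0,
                              spike_amp: float = 1.0, noise_sd: float = 0.015,
                              seed: int | None = None) -> TimeSeries:
    """Loose-patch voltage trace: positive-dominant biphasic unit waveforms
    at the given spike times over white noise — the fixture for spike
    detection (threshold = 3x SD of the >500 Hz trace).

    As in real loose-patch recordings, the unit waveform is tens of times the
    noise floor, so the trace SD is spike-inflated and a 3x SD threshold sits
    several noise SDs above the floor; broadband Gaussian noise would
    otherwise cross a threshold 3x its own SD at a high rate."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = noise_sd * rng.standard_normal(n)
    # monophasic positive unit waveform (capacitive action-current transient)
    n_k = max(int(round(1.0e-3 * fs)), 5)
    tk = (np.arange(n_k) - n_k // 2) / fs * 1e3
    k = np.exp(-tk ** 2 / (2 * 0.10 ** 2)) * spike_amp
    delta = np.zeros(n)
    idx = np.round(np.asarray(spike_times) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(delta, idx, 1.0)
    x += fftconvolve(delta, k, mode="same")
    return TimeSeries(x, fs, 0.0, "loose_patch")


def generate_model_ccg(a: float, b: float, omega: float, mu_ms: float,
                       tau_ms: float, n_total: int,
                       seed: int | None = None,
                       max_lag_ms: float = 50.0) -> Correlogram:
    """Multinomial correlogram with bin probabilities proportional to the
    Gaussian-windowed sinusoid — the controlled fixture for RMI fitting."""
    t = np.arange(-max_lag_ms, max_lag_ms + 1.0)
    y = rmi_model(t, a, b, omega / (2 * np.pi), mu_ms, tau_ms)
    if np.any(y < 0):
        raise ValidationError("model is negative on the lag grid")
    if y.sum() == 0:
        raise ValidationError("model is identically zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_total, y / y.sum())
    return Correlogram(t, counts, "cross", n_total, n_total, 1.0, False)


def generate_drug_condition(cfg: SynthConfig, drug: str
                            ) -> tuple[SynthRecording, SynthRecording]:
    """(baseline, drug) recording pair sharing one event schedule.

    ``ttx`` attenuates spike-derived LFP components; ``gabazine`` removes the
    SWR ripple while leaving unit activity intact; ``riluzole`` slows and
    truncates the stereotyped bursts.
    """
    if drug not in _DRUG_PRESETS:
        raise ValidationError(f"unknown drug {drug!r}; choose from {sorted(_DRUG_PRESETS)}")
    base = generate_recording(cfg)
    treated = generate_recording(cfg, scales=_DRUG_PRESETS[drug], drug=drug)
    return base, treated
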