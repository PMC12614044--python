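"""Spike-level analysis: detection, correlograms, the ripple modulation
index, peri-event histograms, windowed rates, burst segmentation, firing-type
classification and complex-spike-burst (CSB) rate counting.

The ripple modulation index (RMI) quantifies ripple-frequency co-modulation
of a spike correlogram by fitting a Gaussian-windowed sinusoid

    y(t) = (a*sin(omega*t) + b) * exp(-(t - mu)^2 / (2*tau^2))

to the 1 ms-binned counts; RMI = |a| / b, the ratio of the sinusoidal
amplitude to its offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

from .core import CellClass, EventTable, SpikeTrain, TimeSeries, ValidationError
from .filters import _rc_apply

__all__ = [
    "Correlogram", "RMIFit", "PETH", "Burst", "FiringType",
    "detect_spikes", "correlogram", "fit_rmi", "peth", "last_spike_before",
    "windowed_rates", "detect_bursts", "classify_firing_type",
    "first_spike_differences", "csb_rate", "FitError",
    "PRE1_WINDOW", "PRE2_WINDOW", "POST_WINDOW",
]

log = logging.getLogger(__name__)

#: Firing-rate windows relative to IED onset (s): Pre-I, Pre-II, Post-event.
PRE1_WINDOW = (-0.300, -0.150)
PRE2_WINDOW = (-0.150, -0.010)
POST_WINDOW = (0.150, 0.300)


class FitError(RuntimeError):
    pass


class FiringType(Enum):
    TYPE_I = "type_I"
    TYPE_II = "type_II"
    UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# Spike detection

def detect_spikes(trace: TimeSeries, k_sd: float = 3.0, hp_fc: float = 500.0,
                  dead_time: float = 0.001) -> SpikeTrain:
    """Detect spikes in a loose-patch trace.

    Positive-going crossings of ``k_sd`` times the SD of the >500 Hz
    high-passed trace, one spike per crossing with a 1 ms dead time. The
    spike time is the local maximum within the dead-time window after the
    crossing.
    """
    if trace.duration < 0.1:
        raise ValidationError("trace must be at least 100 ms long")
    x = _rc_apply(trace.samples, trace.fs, "high", hp_fc, two_way=True)
    sd = float(np.std(x))
    if sd == 0:
        raise ValidationError("flat trace: SD is 0")
    thr = k_sd * sd
    crossings = np.flatnonzero((x[:-1] < thr) & (x[1:] >= thr)) + 1
    dead = max(int(round(dead_time * trace.fs)), 1)
    times = []
    last = -np.inf
    for i in crossings:
        if i - last < dead:
            continue
        j = i + int(np.argmax(x[i:i + dead]))
        times.append(trace.t0 + j / trace.fs)
        last = i
    log.info("detect_spikes: k_sd=%g sd=%g -> %d spikes", k_sd, sd, len(times))
    return SpikeTrain(np.asarray(times), trace.label or "detected")


# ---------------------------------------------------------------------------
# Correlograms

@dataclass
class Correlogram:
    """Auto- or cross-correlogram at 1 ms resolution.

    ``lags`` holds bin centers in ms; in auto mode the zero-lag bin is
    removed from the arrays entirely (flagged by ``zero_lag_removed``),
    not set to zero.
    """

    lags: np.ndarray
    counts: np.ndarray
    mode: str
    n_ref: int
    n_tgt: int
    bin_ms: float = 1.0
    zero_lag_removed: bool = False


def correlogram(ref: SpikeTrain, tgt: SpikeTrain | None = None,
                max_lag_ms: float = 50.0, bin_ms: float = 1.0) -> Correlogram:
    """Counts of target spikes in 1 ms lag bins around every reference spike.

    Computed over all spikes of the trains (state epochs are selected by
    restricting the trains beforehand, not by event-triggered windowing).
    Auto mode (``tgt is None``) excludes self-pairs and drops the zero-lag
    bin.
    """
    if len(ref) == 0:
        raise ValidationError("reference train is empty")
    mode = "auto" if tgt is None else "cross"
    tgt_t = ref.times if tgt is None else tgt.times
    if tgt_t.size == 0:
        raise ValidationError("target train is empty")
    n_half = int(round(max_lag_ms / bin_ms))
    edges_s = (np.arange(-n_half, n_half + 2) - 0.5) * bin_ms / 1e3
    counts = np.zeros(2 * n_half + 1, dtype=np.int64)
    lo = np.searchsorted(tgt_t, ref.times + edges_s[0])
    hi = np.searchsorted(tgt_t, ref.times + edges_s[-1])
    for t, a, b in zip(ref.times, lo, hi):
        d = tgt_t[a:b] - t
        idx = np.floor(d * 1e3 / bin_ms + 0.5).astype(int) + n_half
        np.add.at(counts, idx[(idx >= 0) & (idx < counts.size)], 1)
    lags = np.arange(-n_half, n_half + 1, dtype=float) * bin_ms
    zero_removed = False
    if mode == "auto":
        counts[n_half] -= len(ref)  # self-pairs
        keep = lags != 0.0
        lags, counts = lags[keep], counts[keep]
        zero_removed = True
    return Correlogram(lags, counts, mode, len(ref), int(tgt_t.size),
                       bin_ms, zero_removed)


def mirrored(ccg: Correlogram) -> Correlogram:
    """correlogram(B, A) from correlogram(A, B): counts reversed in lag."""
    return Correlogram(ccg.lags.copy(), ccg.counts[::-1].copy(), ccg.mode,
                       ccg.n_tgt, ccg.n_ref, ccg.bin_ms, ccg.zero_lag_removed)


# ---------------------------------------------------------------------------
# Ripple modulation index

@dataclass
class RMIFit:
    """Fitted Gaussian-windowed sinusoid and the derived ripple index.

    The sinusoid carries a phase term (``phi``) so that correlograms peaked
    at zero lag — the generic case for synchronized pairs — are fittable;
    a pure odd sinusoid cannot represent an even correlogram.
    """

    a: float            # sinusoid amplitude (counts)
    b: float            # sinusoid offset (counts)
    omega: float        # angular frequency (rad/s)
    phi: float          # sinusoid phase (rad)
    mu_ms: float        # Gaussian center (ms)
    tau_ms: float       # Gaussian width (ms)
    rmi: float          # |a| / b
    rss: float          # residual sum of squares
    capped: bool = False

    @property
    def freq_hz(self) -> float:
        return self.omega / (2.0 * np.pi)


def rmi_model(t_ms: np.ndarray, a: float, b: float, f_hz: float,
              mu_ms: float, tau_ms: float, phi: float = 0.0) -> np.ndarray:
    w = 2.0 * np.pi * f_hz / 1e3  # rad per ms
    return (a * np.sin(w * t_ms + phi) + b) * np.exp(-(t_ms - mu_ms) ** 2 / (2.0 * tau_ms ** 2))


_B_FLOOR = 1e-6


def fit_rmi(ccg: Correlogram, f_init: float = 200.0,
            f_bounds: tuple[float, float] = (140.0, 260.0)) -> RMIFit:
    """Nonlinear least squares of the Gaussian-windowed sinusoid to raw
    correlogram counts.

    For fixed (frequency, Gaussian center, Gaussian width) the model is
    linear in the two sinusoid quadratures and the offset, so candidate
    starts are ranked by profiled linear least squares over a ripple-band
    frequency grid and a set of Gaussian shapes; the best candidates are
    then refined by bounded nonlinear least squares and the lowest residual
    sum of squares is kept.
    """
    t = ccg.lags
    y = ccg.counts.astype(float)
    if t.max() < 25.0 or t.min() > -25.0:
        raise ValidationError("correlogram must span at least +/-25 ms")
    if y.sum() < 100:
        raise ValidationError("need at least 100 counts in the correlogram")

    mu0 = float(np.clip(t[np.argmax(y)], -20.0, 20.0))
    f_cand = np.arange(f_bounds[0] + 2.5, f_bounds[1] - 2.4, 2.5)
    if f_bounds[0] < f_init < f_bounds[1]:
        f_cand = np.unique(np.r_[f_cand, f_init])
    shapes = [(0.0, 10.0), (0.0, 20.0), (0.0, 40.0),
              (mu0, 10.0), (mu0, 20.0), (mu0, 40.0)]
    starts = []
    for mu, tau in shapes:
        G = np.exp(-(t - mu) ** 2 / (2.0 * tau ** 2))
        for f in f_cand:
            w = 2.0 * np.pi * f / 1e3
            A = np.column_stack([np.sin(w * t) * G, np.cos(w * t) * G, G])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            r = y - A @ coef
            rss = float(r @ r)
            p, q, b = coef
            a = float(np.hypot(p, q))
            phi = float(np.arctan2(q, p))
            starts.append((rss, [a, max(b, _B_FLOOR), f, phi, mu, tau]))
    starts.sort(key=lambda s: s[0])

    def resid(p):
        a, b, f, phi, mu, tau = p
        return rmi_model(t, a, b, f, mu, tau, phi) - y

    lb = [0.0, _B_FLOOR, f_bounds[0], -2 * np.pi, -25.0, 1.0]
    ub = [np.inf, np.inf, f_bounds[1], 2 * np.pi, 25.0, 100.0]
    best = None
    for rss0, p0 in starts[:3]:
        p0 = [min(max(v, l), u) for v, l, u in zip(p0, lb, ub)]
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), method="trf",
                                max_nfev=400)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitError("RMI fit did not converge from any start")
    rss, (a, b, f, phi, mu, tau) = best
    capped = b <= 10 * _B_FLOOR
    rmi = abs(a) / max(b, _B_FLOOR)
    if capped:
        rmi = min(rmi, 1e3)
        log.warning("fit_rmi: offset b at the lower bound; RMI capped")
    return RMIFit(float(a), float(b), 2.0 * np.pi * f, float(phi), float(mu),
                  float(tau), float(rmi), rss, capped)


# ---------------------------------------------------------------------------
# Peri-event histograms and rates

@dataclass
class PETH:
    """Peri-event time histogram: pooled counts and per-event spike
    probability in 1 ms bins relative to the trigger."""

    edges_ms: np.ndarray
    counts: np.ndarray
    prob: np.ndarray
    n_events: int
    trigger_kind: str = ""

    @property
    def centers_ms(self) -> np.ndarray:
        return 0.5 * (self.edges_ms[:-1] + self.edges_ms[1:])

    @property
    def bin_ms(self) -> float:
        return float(self.edges_ms[1] - self.edges_ms[0])


def peth(train: SpikeTrain, triggers, window_ms: tuple[float, float] = (-50.0, 50.0),
         bin_ms: float = 1.0, trigger_kind: str = "") -> PETH:
    triggers = np.asarray(list(triggers), dtype=float)
    if triggers.size == 0:
        raise ValidationError("need at least one trigger")
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    any_hit = np.zeros(edges.size - 1, dtype=np.int64)
    for trg in triggers:
        rel = (train.times - trg) * 1e3
        h, _ = np.histogram(rel, bins=edges)
        counts += h
        any_hit += h > 0
    return PETH(edges, counts, any_hit / triggers.size, triggers.size, trigger_kind)


def last_spike_before(train: SpikeTrain, times) -> list[float | None]:
    """Per reference time, the greatest spike time strictly before it."""
    out: list[float | None] = []
    for t in times:
        i = int(np.searchsorted(train.times, t, side="left"))
        out.append(float(train.times[i - 1]) if i > 0 else None)
    return out


def windowed_rates(train: SpikeTrain, ied_onsets) -> dict[str, float]:
    """Firing rates (Hz) in the Pre-I, Pre-II and Post-event windows relative
    to IED onset, pooled over events."""
    onsets = np.asarray(list(ied_onsets), dtype=float)
    if onsets.size == 0:
        raise ValidationError("need at least one IED onset")
    out = {}
    for name, (w0, w1) in (("pre1", PRE1_WINDOW), ("pre2", PRE2_WINDOW),
                           ("post", POST_WINDOW)):
        n = 0
        for t in onsets:
            n += int(np.searchsorted(train.times, t + w1)
                     - np.searchsorted(train.times, t + w0))
        out[name] = n / (onsets.size * (w1 - w0))
    return out


# ---------------------------------------------------------------------------
# Bursts and firing-type classification

@dataclass
class Burst:
    """A maximal run of spikes with short inter-spike intervals."""

    onset: float                 # time of the first spike (s)
    isis_ms: np.ndarray          # ordered intraburst ISIs (ms)

    @property
    def n_spikes(self) -> int:
        return self.isis_ms.size + 1


def detect_bursts(train: SpikeTrain, max_isi_ms: float = 15.0,
                  min_spikes: int = 2) -> list[Burst]:
    """Maximal runs of spikes whose consecutive ISIs are all below
    ``max_isi_ms``, kept when at least ``min_spikes`` long.

    The field has no single numerical definition of a burst; these defaults
    delimit the stereotyped fast-ripple bursts (ISIs of a few ms) and are
    prominently configurable.
    """
    t = train.times
    if t.size < min_spikes:
        return []
    isi_ms = np.diff(t) * 1e3
    short = isi_ms <= max_isi_ms
    bursts = []
    i = 0
    while i < short.size:
        if short[i]:
            j = i
            while j < short.size and short[j]:
                j += 1
            if (j - i + 1) >= min_spikes:
                bursts.append(Burst(float(t[i]), isi_ms[i:j].copy()))
            i = j
        else:
            i += 1
    return bursts


def classify_firing_type(train: SpikeTrain, ied_events: EventTable,
                         fastrip_windows: list[tuple[float, float]],
                         theta: float = 0.2, min_events: int = 10,
                         max_isi_ms: float = 15.0,
                         min_spikes: int = 2) -> FiringType:
    """Classify a pyramidal cell as firing type I or II.

    Type II iff the fraction of IEDs with at least one burst onset in the
    Pre-II window (-150 to -10 ms of IED onset) and outside every fast-ripple
    window exceeds ``theta``. Type I cells burst exclusively inside the
    fast-ripple, when basket cells have fallen silent.
    """
    ied = ied_events.of_kind("IED")
    if len(ied) < min_events:
        return FiringType.UNCLASSIFIED
    onsets = np.where(np.isfinite(ied.onset_times), ied.onset_times, ied.peak_times)
    burst_onsets = np.asarray([b.onset for b in
                               detect_bursts(train, max_isi_ms, min_spikes)])
    n_pre = 0
    for t in onsets:
        if burst_onsets.size == 0:
            break
        rel = burst_onsets - t
        in_pre2 = (rel >= PRE2_WINDOW[0]) & (rel <= PRE2_WINDOW[1])
        cand = burst_onsets[in_pre2]
        cand = [c for c in cand
                if not any(w0 <= c <= w1 for (w0, w1) in fastrip_windows)]
        if cand:
            n_pre += 1
    frac = n_pre / len(ied)
    return FiringType.TYPE_II if frac > theta else FiringType.TYPE_I


def first_spike_differences(train_a: SpikeTrain, train_b: SpikeTrain,
                            ied_events: EventTable,
                            window: tuple[float, float] = (-0.05, 0.1)
                            ) -> np.ndarray:
    """Per IED, first spike of A minus first spike of B (ms), within the
    event window relative to the IED peak; events where either cell is
    silent are skipped."""
    diffs = []
    for t in ied_events.of_kind("IED").peak_times:
        firsts = []
        for tr in (train_a, train_b):
            m = (tr.times >= t + window[0]) & (tr.times <= t + window[1])
            firsts.append(tr.times[m][0] if m.any() else None)
        if firsts[0] is not None and firsts[1] is not None:
            diffs.append((firsts[0] - firsts[1]) * 1e3)
    return np.asarray(diffs)


def csb_rate(spikes_per_step: list, max_isi_ms: float = 15.0,
             min_spikes: int = 3) -> float:
    """Fraction of current-injection steps whose response contains at least
    one complex spike burst (>= 3 spikes with short ISIs)."""
    if len(spikes_per_step) < 3:
        raise ValidationError("need at least 3 current steps")
    n_burst = 0
    for spikes in spikes_per_step:
        tr = spikes if isinstance(spikes, SpikeTrain) else SpikeTrain(np.asarray(spikes, float))
        if detect_bursts(tr, max_isi_ms, min_spikes):
            n_burst += 1
    return n_burst / len(spikes_per_step)
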