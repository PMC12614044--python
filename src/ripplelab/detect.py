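"""Detection of sharp wave-ripples (SWRs) and interictal epileptiform
discharges (IEDs), ripple-cycle trigger selection, fast-ripple onset
estimation, and event-triggered power quantification.

Detection rules:

* SWR peaks: supra-threshold excursions of the 30 Hz low-passed field,
  threshold ``k_sd`` times the SD of that filtered trace (default 5).
* IED peaks: local maxima of the fast-ripple (200-500 Hz) power envelope
  exceeding ``k_sd`` times the SD of the envelope; the IED peak is the peak
  of fast-ripple power.
* Fast-ripple onset: the latest time before the peak at which the envelope
  crosses 5% of the event-local maximum from below.

SD baselines are computed over the whole filtered trace; pass an explicit
``baseline`` span to use an event-free segment instead.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .core import (BandDef, EventTable, TimeSeries, ValidationError,
                   FASTRIP_POWER_BAND, RIPPLE_BAND)
from .filters import PowerEnvelope, band_filter, power_envelope, rc_filter

__all__ = [
    "DetectionError",
    "detect_swr",
    "detect_ied",
    "ripple_trigger_time",
    "add_ripple_triggers",
    "fastrip_onset",
    "fastrip_window",
    "annotate_fastrip_onsets",
    "event_triggered_average",
    "power_change",
    "reconcile_events",
]

log = logging.getLogger(__name__)

#: Smoothing cutoff (Hz) of the envelope used for onset estimation; faster
#: than the detection envelope so the 5% crossing tracks the true rise.
ONSET_SMOOTH_FC = 150.0


class DetectionError(RuntimeError):
    pass


def _threshold_peaks(x: np.ndarray, thr: float, fs: float, t0: float,
                     refractory: float) -> tuple[list[float], list[float]]:
    """One peak per supra-threshold excursion of ``x``, refractory-merged.

    Returns (peak times, peak heights). Merging keeps the larger peak of any
    pair closer than ``refractory`` seconds.
    """
    above = x > thr
    if not above.any():
        return [], []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    peaks, heights = [], []
    for s, e in zip(starts, ends):
        i = s + int(np.argmax(x[s:e]))
        peaks.append(t0 + i / fs)
        heights.append(float(x[i]))
    # refractory merge, keeping the larger of close pairs
    keep_t, keep_h = [], []
    for t, h in zip(peaks, heights):
        if keep_t and t - keep_t[-1] < refractory:
            if h > keep_h[-1]:
                keep_t[-1], keep_h[-1] = t, h
        else:
            keep_t.append(t)
            keep_h.append(h)
    return keep_t, keep_h


def _baseline_sd(x: np.ndarray, fs: float, t0: float,
                 baseline: tuple[float, float] | None) -> float:
    if baseline is None:
        return float(np.std(x))
    i0 = max(int(round((baseline[0] - t0) * fs)), 0)
    i1 = min(int(round((baseline[1] - t0) * fs)), x.size)
    if i1 - i0 < 2:
        raise ValidationError("baseline span contains fewer than 2 samples")
    return float(np.std(x[i0:i1]))


def detect_swr(lfp: TimeSeries, k_sd: float = 5.0, lowpass_fc: float = 30.0,
               refractory: float = 0.05, polarity: str = "abs",
               baseline: tuple[float, float] | None = None) -> EventTable:
    """Detect SWR peak times in the 30 Hz low-passed field.

    ``polarity`` selects the signed convention of the sharp wave: ``"abs"``
    (default), ``"pos"`` or ``"neg"``.
    """
    if lfp.duration < 1.0:
        raise ValidationError("recording must be at least 1 s long")
    filt = rc_filter(lfp, "low", lowpass_fc, two_way=True).samples
    sd = _baseline_sd(filt, lfp.fs, lfp.t0, baseline)
    if sd == 0:
        raise DetectionError("flat signal: SD of the low-passed trace is 0")
    if polarity == "abs":
        x = np.abs(filt)
    elif polarity == "pos":
        x = filt
    elif polarity == "neg":
        x = -filt
    else:
        raise ValueError(f"polarity must be abs/pos/neg, got {polarity!r}")
    thr = k_sd * sd
    peaks, _ = _threshold_peaks(x, thr, lfp.fs, lfp.t0, refractory)
    log.info("detect_swr: k_sd=%g sd=%g thr=%g -> %d events", k_sd, sd, thr, len(peaks))
    return EventTable.from_records(
        [{"kind": "SWR", "peak_time": t, "trigger_time": t, "onset_time": np.nan}
         for t in peaks])


def detect_ied(lfp: TimeSeries, band: BandDef = FASTRIP_POWER_BAND,
               k_sd: float = 8.0, smooth_fc: float = 20.0,
               refractory: float = 0.2,
               baseline: tuple[float, float] | None = None) -> EventTable:
    """Detect IED peaks as maxima of the fast-ripple power envelope."""
    if lfp.duration < 1.0:
        raise ValidationError("recording must be at least 1 s long")
    env = power_envelope(lfp, band, smooth_fc)
    sd = _baseline_sd(env.values, env.fs, env.t0, baseline)
    if sd == 0:
        raise DetectionError("flat signal: SD of the power envelope is 0")
    # The envelope is nonnegative with a noise floor well above its SD, so
    # the k*SD criterion is applied to the mean-subtracted envelope.
    thr = float(np.mean(env.values)) + k_sd * sd
    peaks, _ = _threshold_peaks(env.values, thr, env.fs, env.t0, refractory)
    log.info("detect_ied: band=%s k_sd=%g sd=%g thr=%g -> %d events",
             band.name, k_sd, sd, thr, len(peaks))
    return EventTable.from_records(
        [{"kind": "IED", "peak_time": t, "trigger_time": t, "onset_time": np.nan}
         for t in peaks])


def ripple_trigger_time(lfp: TimeSeries, swr_peak: float,
                        band: BandDef = RIPPLE_BAND,
                        search: float = 0.025) -> float:
    """Negative peak of the ripple cycle closest to the SWR peak.

    Using the trough of the ripple-band trace as trigger preserves ripple
    phase in event-triggered averages. Falls back to ``swr_peak`` with a
    warning when no trough lies within ``search`` seconds.
    """
    if not (lfp.t0 <= swr_peak <= lfp.t_end):
        raise ValidationError("swr_peak outside the recording")
    filt = band_filter(lfp, band, two_way=True).samples
    i0 = max(lfp.index_of(swr_peak - search), 1)
    i1 = min(lfp.index_of(swr_peak + search), len(filt) - 2)
    seg = filt[i0:i1 + 1]
    # local minima with negative value = ripple troughs
    interior = (seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:]) & (seg[1:-1] < 0)
    idx = np.flatnonzero(interior) + 1 + i0
    if idx.size == 0:
        warnings.warn("no ripple trough within the search window; "
                      "using the SWR peak as trigger", stacklevel=2)
        return swr_peak
    t_troughs = lfp.t0 + idx / lfp.fs
    return float(t_troughs[np.argmin(np.abs(t_troughs - swr_peak))])


def add_ripple_triggers(lfp: TimeSeries, events: EventTable,
                        band: BandDef = RIPPLE_BAND,
                        search: float = 0.025) -> EventTable:
    df = events.df.copy()
    df["trigger_time"] = [ripple_trigger_time(lfp, t, band, search)
                          for t in df["peak_time"]]
    return EventTable(df)


def _local_max(env: PowerEnvelope, peak: float, halfwidth: float) -> tuple[int, float]:
    i0 = env.index_of(peak - halfwidth)
    i1 = env.index_of(peak + halfwidth)
    seg = env.values[i0:i1 + 1]
    i = i0 + int(np.argmax(seg))
    return i, float(env.values[i])


def fastrip_onset(env: PowerEnvelope, ied_peak: float, frac: float = 0.05,
                  local_max_halfwidth: float = 0.1,
                  search: float = 0.1) -> float:
    """Time when the power envelope crosses ``frac`` of the event-local
    maximum from below, latest such crossing before the peak."""
    if not (env.t0 <= ied_peak <= env.t_end):
        raise ValidationError("ied_peak outside the envelope span")
    i_max, v_max = _local_max(env, ied_peak, local_max_halfwidth)
    thr = frac * v_max
    if frac >= 1.0:
        return env.t0 + i_max / env.fs
    i0 = env.index_of(env.t0 + i_max / env.fs - search)
    seg = env.values[i0:i_max + 1]
    below = seg < thr
    if not below.any():
        raise DetectionError(
            "envelope never below the onset threshold in the search window")
    i_below = i0 + int(np.flatnonzero(below)[-1])
    # linear interpolation of the crossing between i_below and i_below+1
    v0, v1 = env.values[i_below], env.values[min(i_below + 1, len(env) - 1)]
    t = i_below / env.fs + env.t0
    if v1 > v0:
        t += (thr - v0) / (v1 - v0) / env.fs
    return float(t)


def fastrip_window(env: PowerEnvelope, ied_peak: float, frac: float = 0.05,
                   local_max_halfwidth: float = 0.1,
                   search: float = 0.1) -> tuple[float, float]:
    """(onset, offset) of a fast-ripple event: the 5% crossings flanking
    the event-local power maximum."""
    onset = fastrip_onset(env, ied_peak, frac, local_max_halfwidth, search)
    i_max, v_max = _local_max(env, ied_peak, local_max_halfwidth)
    thr = frac * v_max
    i1 = env.index_of(env.t0 + i_max / env.fs + search)
    seg = env.values[i_max:i1 + 1]
    below = seg < thr
    if not below.any():
        raise DetectionError(
            "envelope never below the offset threshold in the search window")
    i_off = i_max + int(np.flatnonzero(below)[0])
    return onset, env.t0 + i_off / env.fs


def annotate_fastrip_onsets(lfp: TimeSeries, events: EventTable,
                            band: BandDef = FASTRIP_POWER_BAND,
                            smooth_fc: float = ONSET_SMOOTH_FC,
                            frac: float = 0.05) -> EventTable:
    """Fill ``onset_time`` of IED rows with the 5% fast-ripple power crossing."""
    env = power_envelope(lfp, band, smooth_fc)
    df = events.df.copy()
    onsets = []
    for _, row in df.iterrows():
        if row["kind"] != "IED":
            onsets.append(row["onset_time"])
            continue
        try:
            onsets.append(fastrip_onset(env, row["peak_time"], frac))
        except DetectionError:
            onsets.append(np.nan)
    df["onset_time"] = onsets
    return EventTable(df)


def event_triggered_average(x: TimeSeries | PowerEnvelope, triggers,
                            window: tuple[float, float]
                            ) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean of sample-aligned windows around each trigger.

    ``window`` is (pre, post) in seconds relative to the trigger, pre
    typically negative. Triggers whose window exits the recording are dropped
    (count logged). Returns (relative times, averaged trace, n_used).
    """
    vals = x.samples if isinstance(x, TimeSeries) else x.values
    fs, t0 = x.fs, x.t0
    i_pre = int(round(window[0] * fs))
    i_post = int(round(window[1] * fs))
    if i_post <= i_pre:
        raise ValidationError("window must have positive length")
    segs = []
    n_dropped = 0
    for t in triggers:
        i = int(round((t - t0) * fs))
        if i + i_pre < 0 or i + i_post >= vals.size:
            n_dropped += 1
            continue
        segs.append(vals[i + i_pre:i + i_post + 1])
    if n_dropped:
        log.info("event_triggered_average: dropped %d/%d triggers",
                 n_dropped, len(list(triggers)))
    if not segs:
        raise DetectionError("all triggers fell outside the recording")
    rel_t = np.arange(i_pre, i_post + 1) / fs
    return rel_t, np.mean(segs, axis=0), len(segs)


def power_change(lfp_baseline: TimeSeries, lfp_drug: TimeSeries,
                 triggers_base, triggers_drug, band: BandDef,
                 window: tuple[float, float],
                 smooth_fc: float = 20.0) -> float:
    """Percent change of the area under the event-triggered band power.

    ``100 * (AUC_drug - AUC_base) / AUC_base`` where each AUC is the area
    under the event-triggered average of the band power envelope.
    """
    if len(list(triggers_base)) < 5 or len(list(triggers_drug)) < 5:
        raise ValidationError("need at least 5 triggers per condition")
    aucs = []
    for lfp, trig in ((lfp_baseline, triggers_base), (lfp_drug, triggers_drug)):
        env = power_envelope(lfp, band, smooth_fc)
        rel_t, avg, _ = event_triggered_average(env, trig, window)
        aucs.append(float(np.trapezoid(avg, rel_t)))
    if aucs[0] == 0:
        raise DetectionError("baseline AUC is zero; percent change undefined")
    return 100.0 * (aucs[1] - aucs[0]) / aucs[0]


def reconcile_events(swr: EventTable, ied: EventTable,
                     exclusion: float = 0.1) -> EventTable:
    """Merge SWR and IED detections, dropping SWR detections that coincide
    with an IED (the large epileptiform deflection also crosses the sharp-
    wave threshold; the IED label takes precedence)."""
    ied_t = ied.peak_times
    keep = []
    for _, row in swr.df.iterrows():
        if ied_t.size and np.min(np.abs(ied_t - row["peak_time"])) < exclusion:
            continue
        keep.append(row.to_dict())
    merged = EventTable.from_records(keep) if keep else EventTable()
    return merged.concat(ied)
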