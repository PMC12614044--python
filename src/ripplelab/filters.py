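"""Zero-phase RC filtering and rectified-smoothed power envelopes.

The primitive throughout is a first-order (single-pole) RC filter applied
forward and then backward over its own output ("two-way"), which doubles the
effective order and cancels the phase shift — the standard trick for keeping
event and oscillation timing intact in field recordings.

Discretization: with ``dt = 1/fs`` and ``RC = 1/(2*pi*fc)``,

* low-pass:  ``y[n] = alpha*x[n] + (1-alpha)*y[n-1]``, ``alpha = dt/(RC+dt)``
* high-pass: ``y[n] = beta*(y[n-1] + x[n] - x[n-1])``, ``beta = RC/(RC+dt)``

Signal ends are padded by reflection over one filter time constant before
filtering (pad discarded afterwards) to suppress edge transients on short
traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core import BandDef, TimeSeries, ValidationError

__all__ = ["rc_filter", "band_filter", "power_envelope", "PowerEnvelope",
           "DEFAULT_SMOOTH_FC"]

#: Default cutoff (Hz) of the low-pass applied to the rectified band signal.
DEFAULT_SMOOTH_FC = 20.0


@dataclass
class PowerEnvelope:
    """Rectified-smoothed amplitude of a band-filtered trace (mV)."""

    values: np.ndarray
    fs: float
    t0: float
    band: BandDef
    smooth_fc: float

    def __len__(self) -> int:
        return self.values.size

    @property
    def t_end(self) -> float:
        return self.t0 + (self.values.size - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def index_of(self, t: float) -> int:
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.values.size - 1)


def _rc_apply(x: np.ndarray, fs: float, kind: str, fc: float, two_way: bool) -> np.ndarray:
    if not (0 < fc < fs / 2):
        raise ValidationError(f"cutoff {fc} Hz outside (0, Nyquist={fs / 2} Hz)")
    dt = 1.0 / fs
    rc = 1.0 / (2.0 * math.pi * fc)
    if kind == "low":
        alpha = dt / (rc + dt)
        b, a = [alpha], [1.0, -(1.0 - alpha)]
    elif kind == "high":
        beta = rc / (rc + dt)
        b, a = [beta, -beta], [1.0, -beta]
    else:
        raise ValueError(f"kind must be 'low' or 'high', got {kind!r}")

    n_pad = min(max(int(round(rc * fs)), 1), x.size - 1)
    xp = np.pad(x, n_pad, mode="reflect")
    y = lfilter(b, a, xp)
    if two_way:
        y = lfilter(b, a, y[::-1])[::-1]
    return np.asarray(y[n_pad:len(xp) - n_pad])


def rc_filter(ts: TimeSeries, kind: str, fc: float, two_way: bool = True) -> TimeSeries:
    """Single-pole RC filter; ``two_way`` runs it forward then backward."""
    return ts.with_samples(_rc_apply(ts.samples, ts.fs, kind, fc, two_way))


def band_filter(ts: TimeSeries, band: BandDef, two_way: bool = True) -> TimeSeries:
    """High-pass at ``band.f_low`` cascaded with low-pass at ``band.f_high``.

    An infinite ``f_high`` reduces to the high-pass alone.
    """
    y = _rc_apply(ts.samples, ts.fs, "high", band.f_low, two_way)
    if not band.is_highpass:
        y = _rc_apply(y, ts.fs, "low", band.f_high, two_way)
    return ts.with_samples(y)


def power_envelope(ts: TimeSeries, band: BandDef,
                   smooth_fc: float = DEFAULT_SMOOTH_FC) -> PowerEnvelope:
    """Low-pass filtered absolute value of the band-filtered signal.

    This is the power proxy used for event detection, onset estimation and
    drug-effect quantification. ``smooth_fc`` must lie below the band to
    smooth over individual oscillation cycles.
    """
    if smooth_fc >= band.f_low:
        raise ValidationError(
            f"smooth_fc {smooth_fc} Hz must be below the band low edge {band.f_low} Hz")
    rect = np.abs(band_filter(ts, band, two_way=True).samples)
    env = _rc_apply(rect, ts.fs, "low", smooth_fc, two_way=True)
    # Backward smoothing of a nonnegative signal can undershoot slightly.
    np.clip(env, 0.0, None, out=env)
    return PowerEnvelope(env, ts.fs, ts.t0, band, smooth_fc)
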