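"""Morlet wavelet spectra, cross-wavelet power, and wavelet transform
coherence (WTC) with red-noise significance.

The continuous wavelet transform follows the standard Morlet convention
(``omega0 = 6``): scale ``s`` for frequency ``f`` is
``s = (omega0 + sqrt(2 + omega0^2)) / (4*pi*f)``, the transform is computed
in the Fourier domain with the energy normalization that makes the expected
power of unit-variance white noise flat across scales, and the cone of
influence (COI) marks the region within one e-folding time (``sqrt(2)*s``)
of the trace edges.

Coherence is the smoothed cross-spectrum magnitude squared, normalized by
the smoothed auto-spectra:

    C^2 = |S(W_a conj(W_b) / s)|^2 / ( S(|W_a|^2 / s) * S(|W_b|^2 / s) )

with smoothing ``S`` in time (Gaussian, SD = s/sqrt(2)) and across scales
(boxcar spanning 0.6 of a scale decade step grid). Significance thresholds
come from Monte-Carlo AR(1) ("red noise") surrogate pairs whose lag-1
autocorrelations are estimated from the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .core import BandDef, EventTable, TimeSeries, ValidationError

__all__ = [
    "WaveletSpectrum", "CoherenceMap", "default_freqs", "morlet_cwt",
    "event_avg_spectrogram", "cross_wavelet", "wavelet_coherence",
    "coherence_significance", "band_window_coherence",
]

log = logging.getLogger(__name__)

_OMEGA0 = 6.0
_DJ = 1.0 / 12.0  # voices-per-octave spacing assumed by the scale smoother


def _scale_for_freq(f: np.ndarray, omega0: float) -> np.ndarray:
    return (omega0 + np.sqrt(2.0 + omega0 ** 2)) / (4.0 * np.pi * f)


def _fourier_factor(omega0: float) -> float:
    return (omega0 + np.sqrt(2.0 + omega0 ** 2)) / (4.0 * np.pi)


def default_freqs(f_min: float = 50.0, f_max: float = 600.0,
                  voices: int = 12) -> np.ndarray:
    """Log-spaced frequency grid with ``voices`` voices per octave."""
    n = int(np.ceil(np.log2(f_max / f_min) * voices)) + 1
    return f_min * 2.0 ** (np.arange(n) / voices)


@dataclass
class WaveletSpectrum:
    """Time-frequency power (mV^2); ``w`` holds the complex transform when
    retained, ``coi`` the lowest uncontaminated frequency per time point."""

    power: np.ndarray          # (n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    coi: np.ndarray            # Hz per time point
    omega0: float
    w: np.ndarray | None = None

    def coi_mask(self) -> np.ndarray:
        """Boolean (n_freqs, n_times): True where inside the valid region."""
        return self.freqs[:, None] > self.coi[None, :]


@dataclass
class CoherenceMap:
    """Wavelet transform coherence in [0, 1] with optional significance."""

    coh: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    coi: np.ndarray
    omega0: float
    sig_mask: np.ndarray | None = None
    thresholds: np.ndarray | None = None   # per-scale 1-alpha quantile

    def coi_mask(self) -> np.ndarray:
        return self.freqs[:, None] > self.coi[None, :]


def _cwt(x: np.ndarray, fs: float, freqs: np.ndarray,
         omega0: float = _OMEGA0) -> np.ndarray:
    """Complex Morlet CWT, (n_freqs, n_times)."""
    n = x.size
    n_fft = int(2 ** np.ceil(np.log2(n))) * 2  # zero-pad to curb wraparound
    dt = 1.0 / fs
    xf = np.fft.fft(x - x.mean(), n_fft)
    wk = 2.0 * np.pi * np.fft.fftfreq(n_fft, dt)
    scales = _scale_for_freq(freqs, omega0)
    out = np.empty((freqs.size, n), dtype=complex)
    pos = wk > 0
    norm_const = np.pi ** -0.25
    for i, s in enumerate(scales):
        psi_hat = np.zeros(n_fft)
        psi_hat[pos] = (norm_const * np.sqrt(2.0 * np.pi * s / dt)
                        * np.exp(-0.5 * (s * wk[pos] - omega0) ** 2))
        out[i] = np.fft.ifft(xf * psi_hat)[:n]
    return out


def _coi_freqs(n: int, fs: float, omega0: float) -> np.ndarray:
    """Lowest valid frequency per time point (inf at the very edges)."""
    dt = 1.0 / fs
    d = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    ff = _fourier_factor(omega0)
    with np.errstate(divide="ignore"):
        return ff * np.sqrt(2.0) / np.maximum(d, 0.0)


def _check_freqs(ts: TimeSeries, freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValidationError("freqs must be strictly increasing")
    if freqs[0] <= 1.0 / ts.duration or freqs[-1] >= ts.fs / 2:
        raise ValidationError(
            f"freqs must lie within (1/duration, Nyquist) = "
            f"({1.0 / ts.duration:.3g}, {ts.fs / 2:.3g}) Hz")
    return freqs


def morlet_cwt(ts: TimeSeries, freqs: np.ndarray, omega0: float = _OMEGA0,
               keep_complex: bool = False) -> WaveletSpectrum:
    """Morlet wavelet power of an unfiltered trace at each (time, freq)."""
    freqs = _check_freqs(ts, freqs)
    w = _cwt(ts.samples, ts.fs, freqs, omega0)
    return WaveletSpectrum(np.abs(w) ** 2, freqs, ts.times(),
                           _coi_freqs(len(ts), ts.fs, omega0), omega0,
                           w if keep_complex else None)


def event_avg_spectrogram(ts: TimeSeries, triggers, window: tuple[float, float],
                          freqs: np.ndarray, normalize: bool = False,
                          omega0: float = _OMEGA0) -> WaveletSpectrum:
    """Mean over events of windowed wavelet power, aligned to the trigger.

    Each event is transformed on a margin-padded segment so edge effects stay
    outside the averaged window. With ``normalize``, each frequency row of
    the average is divided by its own window mean (dimensionless), the
    display convention for event-aligned spectrograms.
    """
    freqs = np.asarray(freqs, dtype=float)
    margin = np.sqrt(2.0) * _scale_for_freq(freqs[:1], omega0)[0] * 3.0
    i_pre = int(round((window[0] - margin) * ts.fs))
    i_post = int(round((window[1] + margin) * ts.fs))
    n_m = int(round(margin * ts.fs))
    acc = None
    n_used = 0
    for t in triggers:
        i = int(round((t - ts.t0) * ts.fs))
        if i + i_pre < 0 or i + i_post >= len(ts):
            continue
        seg = ts.samples[i + i_pre:i + i_post + 1]
        p = np.abs(_cwt(seg, ts.fs, freqs, omega0)) ** 2
        p = p[:, n_m:p.shape[1] - n_m]
        acc = p if acc is None else acc + p
        n_used += 1
    if acc is None:
        raise ValidationError("no trigger window fits inside the recording")
    avg = acc / n_used
    if normalize:
        row_mean = avg.mean(axis=1, keepdims=True)
        avg = np.divide(avg, row_mean, out=np.ones_like(avg), where=row_mean > 0)
    rel_t = np.arange(i_pre + n_m, i_post - n_m + 1) / ts.fs
    coi = _coi_freqs(avg.shape[1], ts.fs, omega0)
    return WaveletSpectrum(avg, freqs, rel_t, coi, omega0)


def _check_pair(a: TimeSeries, b: TimeSeries) -> None:
    if a.fs != b.fs or len(a) != len(b):
        raise ValidationError("the two channels must share fs and length")


def cross_wavelet(a: TimeSeries, b: TimeSeries, freqs: np.ndarray,
                  omega0: float = _OMEGA0) -> WaveletSpectrum:
    """Cross-wavelet power |W_a * conj(W_b)| of two simultaneous traces."""
    _check_pair(a, b)
    freqs = _check_freqs(a, freqs)
    wa = _cwt(a.samples, a.fs, freqs, omega0)
    wb = _cwt(b.samples, b.fs, freqs, omega0)
    wxy = wa * np.conj(wb)
    return WaveletSpectrum(np.abs(wxy), freqs, a.times(),
                           _coi_freqs(len(a), a.fs, omega0), omega0, wxy)


def _smooth(z: np.ndarray, scales: np.ndarray, fs: float) -> np.ndarray:
    """Time (per-scale Gaussian) then scale (boxcar) smoothing."""
    out = np.empty_like(z)
    for i, s in enumerate(scales):
        sigma = s * fs / np.sqrt(2.0)
        out[i] = gaussian_filter1d(z[i].real, sigma, mode="reflect")
        if np.iscomplexobj(z):
            out[i] = out[i] + 1j * gaussian_filter1d(z[i].imag, sigma, mode="reflect")
    n_box = max(int(round(0.6 / _DJ)), 1)
    if np.iscomplexobj(z):
        out = (uniform_filter1d(out.real, n_box, axis=0, mode="nearest")
               + 1j * uniform_filter1d(out.imag, n_box, axis=0, mode="nearest"))
    else:
        out = uniform_filter1d(out, n_box, axis=0, mode="nearest")
    return out


def wavelet_coherence(a: TimeSeries, b: TimeSeries, freqs: np.ndarray,
                      omega0: float = _OMEGA0) -> CoherenceMap:
    """Wavelet transform coherence of two simultaneous traces, in [0, 1]."""
    _check_pair(a, b)
    freqs = _check_freqs(a, freqs)
    scales = _scale_for_freq(freqs, omega0)
    wa = _cwt(a.samples, a.fs, freqs, omega0)
    wb = _cwt(b.samples, b.fs, freqs, omega0)
    inv_s = (1.0 / scales)[:, None]
    s_xy = _smooth(wa * np.conj(wb) * inv_s, scales, a.fs)
    s_aa = _smooth((np.abs(wa) ** 2) * inv_s, scales, a.fs)
    s_bb = _smooth((np.abs(wb) ** 2) * inv_s, scales, a.fs)
    denom = s_aa * s_bb
    coh = np.divide(np.abs(s_xy) ** 2, denom,
                    out=np.zeros_like(s_aa), where=denom > 0)
    np.clip(coh, 0.0, 1.0, out=coh)
    return CoherenceMap(coh, freqs, a.times(),
                        _coi_freqs(len(a), a.fs, omega0), omega0)


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    r = float(np.dot(x[:-1], x[1:]) / denom)
    if abs(r) >= 1.0:
        log.warning("degenerate AR(1) estimate |r| >= 1; clipping")
        r = float(np.clip(r, -0.999, 0.999))
    return r


def _ar1(rng: np.random.Generator, r: float, n: int) -> np.ndarray:
    innov = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = innov[0] / np.sqrt(max(1.0 - r * r, 1e-12))
    for i in range(1, n):
        x[i] = r * x[i - 1] + innov[i]
    return x


def coherence_significance(cmap: CoherenceMap, a: TimeSeries, b: TimeSeries,
                           n_surrogates: int = 300, alpha: float = 0.05,
                           seed: int | None = None) -> CoherenceMap:
    """Per-scale coherence thresholds from AR(1) ("red noise") surrogate
    pairs with lag-1 autocorrelations estimated from the data; the
    significance mask flags in-COI pixels above the 1-alpha quantile."""
    rng = np.random.default_rng(seed)
    ra, rb = _lag1_autocorr(a.samples), _lag1_autocorr(b.samples)
    n = len(a)
    per_scale: list[list[np.ndarray]] = [[] for _ in cmap.freqs]
    for _ in range(n_surrogates):
        sa = TimeSeries(_ar1(rng, ra, n), a.fs, a.t0)
        sb = TimeSeries(_ar1(rng, rb, n), a.fs, a.t0)
        m = wavelet_coherence(sa, sb, cmap.freqs, cmap.omega0)
        valid = m.coi_mask()
        for i in range(cmap.freqs.size):
            per_scale[i].append(m.coh[i][valid[i]])
    thresholds = np.array([
        np.quantile(np.concatenate(v), 1.0 - alpha) if v and sum(len(x) for x in v)
        else np.inf
        for v in per_scale])
    if alpha >= 1.0:
        thresholds = np.full(cmap.freqs.size, -np.inf)
    mask = (cmap.coh > thresholds[:, None]) & cmap.coi_mask()
    return CoherenceMap(cmap.coh, cmap.freqs, cmap.times, cmap.coi,
                        cmap.omega0, mask, thresholds)


def band_window_coherence(cmap: CoherenceMap, events: EventTable,
                          band: BandDef, half_window: float) -> np.ndarray:
    """Per-event mean coherence over (peak +/- half_window) x band."""
    f_sel = (cmap.freqs >= band.f_low) & (cmap.freqs <= band.f_high)
    if not f_sel.any():
        raise ValidationError(f"no frequencies inside band {band.name}")
    out = []
    t = cmap.times
    for pk in events.peak_times:
        t_sel = (t >= pk - half_window) & (t <= pk + half_window)
        if not t_sel.any():
            raise ValidationError("event window outside the coherence map")
        out.append(float(cmap.coh[np.ix_(f_sel, t_sel)].mean()))
    return np.asarray(out)
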