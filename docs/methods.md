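# Methods

This note documents the models and procedures `ripplelab` implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions taken where the design was open.

## Filtering

The primitive filter is a first-order (single-pole) RC stage discretized as
`y[n] = α·x[n] + (1−α)·y[n−1]` (low-pass, `α = dt/(RC+dt)`) or
`y[n] = β·(y[n−1] + x[n] − x[n−1])` (high-pass, `β = RC/(RC+dt)`), with
`RC = 1/(2πfc)`. "Two-way" application runs the filter forward and then
backward over its own output, cancelling the phase response exactly and
doubling the effective order; all detection and power measurements use
two-way filtering so event timing is unbiased. Signal ends are padded by
reflection over one filter time constant before filtering (pad discarded),
which suppresses edge transients on short traces.

Consequences of the first-order design worth knowing:

* Each two-way pass contributes |H|², so the 150–250 Hz band cascade has a
  mid-band gain of ~0.35 at 200 Hz, not ~1; absolute in-band amplitudes are
  attenuated (ratios and indices are unaffected).
* Roll-off is 12 dB/octave per two-way stage. Out-of-band rejection is
  therefore gentle: a 30 Hz sharp wave of amplitude A leaks roughly
  0.01·A into a 200 Hz high-passed trace, and a 200 Hz ripple leaks
  substantially into a 200–500 Hz band. Several detection thresholds below
  are set with this leakage in mind.

Band power is quantified as the **rectified-smoothed envelope**: the
absolute value of the band-filtered trace, low-pass filtered two-way. The
smoothing cutoff is 20 Hz for detection and drug-effect envelopes and
150 Hz (`ONSET_SMOOTH_FC`) for fast-ripple **onset** estimation — a 20 Hz
envelope rises tens of milliseconds before the burst and cannot localize a
5% crossing to the required millisecond scale. Both cutoffs are exposed.

## Event detection

* **SWR**: peaks of the |30 Hz low-passed| field exceeding `k_sd` × SD of
  that filtered trace (default 5), one peak per supra-threshold excursion,
  50 ms refractory merge keeping the larger peak. The SD is computed over
  the whole trace (so the events inflate their own baseline); an explicit
  event-free `baseline` span can be passed instead. Sharp-wave polarity is
  configurable (`abs`/`pos`/`neg`; default absolute value).
* **IED**: local maxima of the fast-ripple (200–500 Hz) power envelope.
  Because the envelope is a nonnegative quantity whose noise-floor *mean*
  is several times its SD, the threshold is `mean + k_sd·SD` of the
  envelope with `k_sd = 8` by default. This keeps the detector silent on
  SWR-only recordings (where sharp-wave and ripple leakage through the
  first-order band filter would cross a lower threshold) while mixed
  recordings place true fast-ripples >25 SD above the mean. 200 ms
  refractory.
* **Reconciliation**: the large IED deflection also crosses the sharp-wave
  threshold, so in mixed recordings SWR detections within 100 ms of an IED
  detection are dropped (the IED label wins). The original experiments
  recorded the two event types in different K⁺ conditions and never faced
  this; the rule is our mixed-recording operationalization.
* **Ripple trigger**: the trough (negative local minimum) of the 150–250 Hz
  filtered trace nearest the SWR peak, searched within ±25 ms; used as the
  trigger for averages so ripple phase survives averaging. Falls back to
  the SWR peak with a warning if no trough is found.
* **Fast-ripple onset/offset**: the latest upward crossing of 5% of the
  event-local envelope maximum before the peak (and the first downward
  crossing after it), searched within 100 ms; linear interpolation between
  samples.
* **Drug quantification**: `100·(AUC_drug − AUC_baseline)/AUC_baseline`,
  AUC being the area under the event-triggered average of the band power
  envelope. With first-order filters the ripple-band AUC at an SWR contains
  a sharp-wave leakage floor, which attenuates measured ripple-power drops
  relative to what steeper filters would report; directions and contrasts
  are unaffected.

## Correlograms and the ripple modulation index

Correlograms count target spikes in 1 ms lag bins around every reference
spike over whole state epochs (no event-triggered windowing).
Autocorrelograms exclude self-pairs and drop the zero-lag bin from the
arrays entirely.

The ripple modulation index is obtained by fitting

    y(t) = (a·sin(ωt + φ) + b) · exp(−(t − μ)²/(2τ²))

to the raw counts over ±50 ms and reporting RMI = |a|/b. The phase term φ
is required: a pure odd sinusoid cannot represent a correlogram peaked at
zero lag, which is precisely the signature of a synchronized pair. Fitting
uses the fact that the model is linear in the quadratures (a·cosφ, a·sinφ)
and the offset b for fixed (ω, μ, τ): candidate starts are ranked by
profiled linear least squares over a 2.5 Hz frequency grid spanning
140–260 Hz and six Gaussian shapes, and the best three are refined by
bounded nonlinear least squares (b > 0, τ ∈ 1–100 ms, μ ∈ ±25 ms). Raw
counts are fitted (no normalization), and the estimator sits at the
statistical (Cramér–Rao) limit for this model: at 5000 total counts the
standard error of a/b is ≈ 0.02 regardless of the true ratio, and the
best-fit-over-frequencies construction gives the null (a = 0) estimate a
positive bias of up to ~0.05. Ratios below ~0.05 are therefore not
distinguishable from zero at that count; state *contrasts* (synchronized
RMI > 1 vs desynchronized < 0.2 on the synthetic conditions) are robust.

## Windowed rates, bursts, classification

Firing-rate windows relative to IED onset: Pre-I (−300…−150 ms), Pre-II
(−150…−10 ms), Post (+150…+300 ms), pooled over events. Bursts are maximal
spike runs with consecutive ISIs ≤ 15 ms and ≥ 2 spikes (≥ 3 for
complex-spike-burst counting in current-step protocols); the field has no
single numerical burst definition, so these are prominently configurable.
A pyramidal cell is classified **type II** when the fraction of IEDs with a
burst onset inside Pre-II and outside every fast-ripple window exceeds
θ = 0.2, else **type I**; cells with fewer than 10 IEDs are unclassified.
θ = 0.2 tolerates occasional spontaneous bursts of type-I cells; the
original assignment was by expert inspection, and this rule is an
operationalization of it.

## Wavelet spectra and coherence

Morlet CWT with ω₀ = 6, computed in the Fourier domain with the energy
normalization that makes unit-variance white noise flat (expected power 1)
across scales; scale s = (ω₀ + √(2+ω₀²))/(4πf); cone of influence at one
e-folding time (√2·s) from the edges. The default frequency grid is
log-spaced at 12 voices per octave.

Wavelet transform coherence follows the standard smoothing convention:
|S(W_a·conj(W_b)/s)|² / (S(|W_a|²/s)·S(|W_b|²/s)) with a per-scale Gaussian
time smoother (SD = s/√2) and a boxcar across scales spanning 0.6 of a
scale octave grid. With this amount of smoothing the coherence of
independent noise sits near 0.4 (limited degrees of freedom), and
co-occurring but independent transients bias it slightly further upward —
absolute values depend on the smoothing spans, contrasts do not.
Significance is assessed by Monte-Carlo AR(1) ("red noise") surrogate
pairs whose lag-1 autocorrelations are estimated from the data: per-scale
1−α quantiles of in-COI surrogate coherence (default 300 surrogates,
α = 0.05). The surrogate route is self-contained and directly calibratable,
which the asymptotic χ² formula is not. Event statistics average coherence
over peak ± 25 ms × 150–250 Hz for SWRs and ± 50 ms × 250–500 Hz for IEDs.

## Pseudosynchrony Monte Carlo

Each of 10,000 repetitions draws a cell class (deep, i.e. type II, with
probability 0.30), one intraburst ISI sequence of that class from the burst
library, and an onset offset from the first-spike onset distribution
(empirical resampling when data are present, else N(0.24, 1.65) ms); spike
times are the offset plus cumulative ISIs, accumulated into a 1 ms
population PETH. ISI-shuffled controls permute each sequence's ISI order
(multiset and duration preserved).

**Periodicity scoring.** Two components of a burst PETH carry no
information about periodicity yet dominate a naive spectrum: the
onset-aligned initial transient (a sharp coherent bump that the shuffled
control retains in full), and the smooth burst envelope, whose harmonics
exceed any fast-ripple line below ~200 Hz. `periodicity_score` therefore
analyzes the PETH tail from just past its global maximum, subtracts a 3 ms
Gaussian-smoothed copy (whose transfer at fast-ripple frequencies is
negligible, so genuine lines pass while envelope and truncation-edge
leakage cancel), and takes the zero-padded power spectrum of the residual.
The modulation depth is the in-band (default 200–350 Hz) peak power divided
by the total spike count — the shot-noise floor, since temporally
unstructured spikes have expected residual power equal to their count at
every frequency — and is reported only when the peak is significant at
α = 10⁻³ against the maximum of independent exponential noise cells;
otherwise the depth is 1 ("no modulation"). This gives depth ≈ 1 for flat,
shuffled and strongly jittered PETHs, large values for stereotyped bursts
at millisecond onset jitter, and a monotone decay with jitter.

## The synthetic generator

The generator's core commitment mirrors the two proposed mechanisms: the
SWR ripple is an *injected*, phase-shared 150–250 Hz oscillation (standing
in for rhythmic perisomatic inhibition), whereas the fast-ripple is *never
injected* — it emerges from summing biphasic extracellular waveforms of
stereotyped pyramidal bursts whose onsets jitter by 0.24 ± 1.65 ms.

Defaults (all configurable): 60 s at 10 kHz; SWRs at 20/min — sharp wave
2.8 mV (Gaussian SD 18 ms, negative), ripple 0.04 mV at 200 Hz over a
20-cycle envelope, shared phase across electrodes, plus a cluster of narrow
(>500 Hz) multi-unit waveforms; IEDs at 10/min — a shared slow deflection
(two Gaussians: 8 ms rise, 35 ms decay) plus 80 bursting cells per
electrode (independent pools per electrode), 5-spike bursts with first ISI
3.6 ms lengthening ×1.3 per step, 10% per-ISI noise, 5% per-burst tempo
factor, 1.0 mV first-spike amplitude decrementing ×0.65 per spike (the
complex-spike-burst decrement; this is also what keeps the fast-ripple
envelope unimodal). Background: 1/f noise (SD 0.05 mV) whose spectrum
steepens to 1/f² above 150 Hz — extracellular spectra do fall faster at
high frequency, and a pure 1/f background would put slowly modulated power
into the fast-ripple band — plus white noise (SD 0.03 mV). Loose-patch
trains: PVBCs (8 Hz baseline) spike at shared ripple troughs during SWRs
(p = 0.8, 0.4 ms jitter), ramp from 5 to 40 Hz before IED onset, and are
silenced (depolarization block) from just before the fast-ripple to 100 ms
after onset; type-I PCs burst only inside fast-ripple windows; type-II PCs
additionally burst before events (probability 0.15 in Pre-I, 0.5 in
Pre-II) and are refractory for 300 ms afterwards.

Event amplitudes were calibrated once so that embedded events sit at or
above 8× the SD of their detection trace — the regime in which threshold
detection is expected to be essentially perfect, matching the supervised
detections of slice experiments. Note that with whole-trace SDs (events
included) this ratio has a ceiling near 8–10 at these event rates: the
events are their own largest SD contribution.

**Ground truth.** Each IED's reference peak and onset are defined by
applying the analysis convention — fast-ripple envelope peak, and the
latest 5% upward crossing — to the *noise-free* burst component of the
LFP. Detection errors measured against these marks isolate the effect of
noise and event overlap; naive marks (first spike, mean spike time)
disagree with any power-based estimator by >5 ms for systematic reasons
(envelope smoothing, flat-topped events). First-spike times and per-cell
burst onsets are stored separately.

**Drug conditions** share the baseline's random draws and scale components:
GABA-A block removes the ripple (spiking intact); Na-channel block
attenuates spike-derived components to 35% (ripple to 75%); burst slowing
scales ISIs ×1.6 and drops one spike per burst.

**What the generator does not emulate:** absolute voltages of real slices;
gradual spike-amplitude decline during depolarization block (block is a
hard silence window); within-event ripple frequency chirps; electrode
drift, line noise and movement artifacts; overlapping event types at one
instant (schedules keep a minimum separation). Passing tests therefore
demonstrate correctness of the analysis chain under the assumed statistical
structure, not robustness to every pathology of real recordings.

## Validation experiment sizes

The closed-loop experiments in `ripplelab.validation` use: 60 s recordings
at 10 kHz for detection, coherence contrast and drug directions (coherence
maps computed after decimation to 2 kHz); a 240 s epileptiform recording
with 20 type-I + 10 type-II cells for classification; 20 repetitions per
cell of a 12-point modulation-ratio × frequency grid (5000-count
correlograms) plus 60 null correlograms for RMI recovery; 300 AR(1)
surrogates and 20 test pairs (4 s at 500 Hz) for coherence calibration;
and 10,000 Monte-Carlo repetitions for pseudosynchrony. These sizes were
chosen as the smallest at which the measured quantities are stable across
seeds.

## Known limitations

* First-order RC filtering is the reference path by design; its shallow
  roll-off leaks sharp-wave energy into high bands and attenuates in-band
  amplitudes. Users needing sharper selectivity should treat the band
  filters as qualitative.
* RMI values below ~0.05 are not statistically distinguishable from zero
  at a few thousand correlogram counts (see above).
* The red-noise significance test calibrates the pixel-wise false-positive
  rate; it does not correct for the multiplicity of pixels in a map.
* Burst delimitation (15 ms / ≥2 spikes) and the classification threshold
  θ are operational conventions, not measured constants.
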