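# Methods

This package re-implements, as a tested pipeline over synthetic data, the
analysis of laminar hippocampal CA1 recordings from a large-animal model of
concussion: per-unit electrophysiological metrics, putative cell-class
assignment, spike–LFP entrainment, group power spectra, epileptiform event
detection, and a biophysical model of a fast-spiking PV⁺ basket cell used to
attribute the measured interneuron changes to a shift in sodium-channel
inactivation. The original animal recordings are not publicly available, so
a synthetic-data generator with known ground truth stands in for them; the
printed group-level values from the study are used as generator defaults and
as worked-example inputs.

## Synthetic laminar recordings (`ca1lamina.synth`)

**LFP.** Each channel is 1/f^α Gaussian background noise (FFT-shaped, RMS
`noise_amplitude_uv`, α = 1 by default) plus a set of narrowband
oscillators. An oscillator is either a pure sinusoid at its band centre or a
band-limited Gaussian process, synchronous across channels and scaled by a
Gaussian depth profile over channel index (laminar amplitude profiles are
not parameterized numerically in the source data, so a unimodal profile
centred on the pyramidal layer is assumed). The generator returns the
per-sample ground-truth phase of every oscillator band. The probe's top
third is annotated as the CA1 pyramidal layer, the bottom third as
below-layer (toward dentate).

**Spike trains.** Units are drawn by point-process thinning — exact, with no
time-discretization bias — from the intensity

    λ(t) = r · exp(κ · cos(φ(t) − φ₀)) / I₀(κ),

where φ(t) is the ground-truth oscillator phase. The I₀ normalization makes
the long-run mean rate exactly `r` regardless of κ, and the expected mean
vector length of the spike phases is the analytic von Mises resultant
I₁(κ)/I₀(κ). Interneurons are tonic; pyramidal cells are burst-renewal
processes (phase-modulated Poisson event onsets; each event is, with
probability `burst_prob`, a burst of geometric length with gamma-jittered
intra-burst intervals; the onset rate is scaled so the mean spike rate stays
`r`). Per-class inter-spike-interval and burst statistics were not reported
for this preparation, so burst parameters are free, plausibility-chosen
constants (35% burst events, 5 ms intra-burst interval, mean burst length
3), not calibrated claims. Waveform templates are negative Gaussians sampled
at 32 kHz (the acquisition rate), so the half-amplitude width equals the
Gaussian FWHM and amplitude/width ground truth is closed-form; each unit
jitters its template by 5%. Every unit has its own random stream derived
from (master seed, stream key, unit index), so adding units does not perturb
existing ones and a fixed seed is bit-reproducible.

**Study-condition presets.** `control_config` / `post_mtbi_config` set the
class means to the measured group values: pyramidal 2.27 Hz / 0.336 ms /
256 µV vs 1.70 / 0.280 / 238 after injury; interneuron 7.46 Hz / 0.373 ms /
367 µV vs 3.09 / 0.263 / 170 (3.78 and 2.33 Hz for the ~190 and ~260 rad/s
velocity subgroups). Locking concentrations are set so the expected MVLs
equal the printed entrainment means (κ ≈ 2·MVL for small κ): pyramidal
62–82 Hz 0.020 → 0.005, 103–117 Hz 0.018 → 0.003; interneuron 4–6 Hz
0.013 → 0.041. The injured preset reduces the 35–75 Hz oscillator amplitude
by 40% and attenuates the high-frequency component. Rate dispersions across
units (CV 0.5 pyramidal, 0.3 interneuron) are chosen as realistic
heterogeneity; they are not fitted.

**Events.** Injectable ground-truth events: a sustained negative DC shift
with raised-cosine ramps (depolarizing shift), and a synchronized train of
sharp negative transients at 6–8 Hz (paroxysmal rhythmic spikes).

What the generator does **not** emulate: spike-sorting artifacts (overlap,
drift, contamination), biophysical forward models of extracellular fields,
non-stationarity of anesthesia depth, correlated noise across channels, and
any within-class correlation structure beyond the configured locking. Tests
passing on this generator therefore validate the estimators and detectors,
not the biological claims.

## Per-unit metrics (`ca1lamina.metrics`)

Firing rate is spike count over recording duration. The autocorrelogram
bins ordered spike-pair lags at 1 ms over 1–50 ms and normalizes to a
probability distribution; its first moment is the probability-weighted mean
lag (small for bursty, large for tonic units). Spike amplitude is the
unsigned baseline-to-extremum deviation, with baseline defined as the mean
of the first 25% of waveform samples (the source analysis does not define
"baseline"; extracellular somatic spikes are trough-dominant, so the
extremum is taken as the largest absolute deviation and polarity is
ignored). Spike width is measured at half amplitude with linear
interpolation between samples (sub-sample precision at 32 kHz). The wavelet
high-pass used to condition wideband signals is a level-6 Daubechies-4
multilevel decomposition with the coarsest approximation zeroed. Zero-spike
units propagate as excluded, not as 0 Hz rows.

## Classification (`ca1lamina.classify`)

Anatomical gate first: units below the annotated pyramidal layer are
excluded as putative dentate cells. Then the rate rule: at or below 7 Hz →
pyramidal, above → interneuron (the boundary is inclusive on the pyramidal
side). The manual waveform/autocorrelogram review is not quantified in the
source protocol; it is determinized here as a guard band: calls within
±1 Hz of the boundary whose autocorrelogram first moment falls on the wrong
side of the population median are labeled unclassifiable. The automated
cross-check is k-means (k = 2) on z-scored (log rate, spike width, first
moment) with 10 restarts and a fixed seed; the higher-rate cluster is
labeled interneuron, and a silhouette score flags degenerate one-cluster
data.

Known limitation, by design: the injured-group interneurons have mean rates
below 7 Hz, so the rate rule — stated for the control regime under
anesthesia — misassigns them; the cohort analysis therefore evaluates
classification against ground truth on the control-like regime and uses
generator ground-truth classes for group statistics.

## Entrainment (`ca1lamina.entrainment`)

Phase extraction is a zero-phase Butterworth band-pass (order 3) followed by
the analytic-signal angle, with phase 0 at the oscillation peak; the method
is a documented, swappable choice (the source names only the MVL itself).
MVL is |n⁻¹ Σ exp(iφ_k)|. The band grid is contiguous over 1–300 Hz, 1 Hz
wide below 12 Hz and 5 Hz wide above — whether the published 4–6 / 62–82 /
103–117 Hz ranges come from a pre-set grid or post-hoc merging is unstated,
so merging of contiguous significant bands (Mann-Whitney, p < 0.05) is
implemented. Spikes within two cycles of a band's low edge of either
recording edge are dropped from the phase pool. No small-sample MVL bias
correction is applied (raw MVL is reported; group sizes are comparable);
under uniform phases E[MVL] ≈ √(π/4n), which the tests verify.

Because raw MVL is used, a unit's value sits on a chance floor that grows as
its spike count shrinks. In the synthetic cohort (120 s recordings) the
injured units fire several-fold less than controls, so their chance floor
(≈ 0.04 at ~400 spikes) exceeds the configured locking levels and dominates
the group comparison; the cohort driver prints the per-group chance levels
alongside the ranges for exactly this reason. The estimator itself is
validated at matched spike counts (the analytic Bessel-ratio and
chance-level oracles), where the comparison is unbiased. Any real-data use
with unequal rates faces the same trade-off between raw MVL and a
spike-count-matched or bias-corrected variant.

## Spectra and events (`ca1lamina.spectral`)

The pyramidal layer is localized as the argmax of per-channel RMS power in
the 600–6000 Hz band of the wideband signal, with a max/median flatness
flag. PSDs are Welch estimates (2 s Hann windows, 50% overlap — the source
toolkit's parameters are unpublished, so the estimator is configurable),
restricted to ≤ 300 Hz, computed on unit-bearing channels with duplicates
excluded. Group comparison: per-animal channel-averaged log power, z-scored
along the frequency axis per curve (the normalization axis is a documented
choice), per-frequency two-sample t-tests at α = 0.01, with contiguous runs
of at least 3 bins merged into reported ranges. The 58–62 Hz mains band is
excluded from testing and interpolated in curves (the original removed it
manually). p-values are deliberately uncorrected for multiple comparisons,
mirroring the source analysis, and every reported range carries an explicit
`multiple_comparison_corrected: false` flag. Note that per-curve z-scoring
makes a genuine power reduction in one band appear as a compensatory
increase elsewhere; directions must be read per range.

The event detectors are this package's own algorithms, anchored to the
qualitative published criteria (sustained > 1 s negative deflection across
the lamina; synchronized 6–8 Hz activity across layers):

- **Depolarizing shift**: per channel, < 2 Hz low-pass, decimation to 50 Hz,
  rolling-median baseline (15 s window); a sample is deviant below baseline
  − 5·MAD; an event needs ≥ 75% of channels deviant simultaneously for
  ≥ 1 s. Boundaries are refined at 40% of peak deflection (calibrated
  against injected ground truth; the MAD crossing sits low on the ramps).
- **Paroxysmal rhythmic spikes**: 6–8 Hz band power (squared analytic
  envelope) per channel against a median + 5·MAD threshold; an event needs
  ≥ 75% of channels above threshold for ≥ 3 cycles. The criterion is
  power-based and phase-blind by specification: co-elevated but asynchronous
  channels still count. Boundaries are refined at 10% of peak median power
  (≈ one third of peak envelope amplitude), compensating the narrowband
  filter's envelope smearing.

All detector constants (MAD multipliers, channel fractions, windows,
refinement fractions) are exposed parameters; defaults were calibrated once
on injected ground truth and give zero false positives over twenty 100 s
clean synthetic backgrounds.

The two detectors are not mutually exclusive: a sharp DC step carries
transient 6–8 Hz edge energy, and a dense train of negative transients
carries a net negative DC component, so each event type can also trigger
the other detector when both occur in one recording. No cross-veto is
applied — in real epileptiform data the two phenomena genuinely co-occur —
but round-trip validation injects each event type separately.

## Fast-spiking PV⁺ cell model (`ca1lamina.pvcell`)

A deterministic single-compartment Hodgkin-Huxley model (leak + Na m³h +
delayed-rectifier K n⁴) replaces the cited multi-compartment basket-cell
simulation; this removes a heavyweight simulator dependency while keeping
the mechanistic claim under test — that a hyperpolarizing shift of sodium
inactivation jointly reduces firing rate, spike width and spike amplitude.
Consequences: the reference factor table's numeric entries are treated as
directional targets, and rows that perturbed selected dendritic sections
are applied whole-cell and flagged non-comparable.

Sodium activation is instantaneous (m = m_inf) with a Boltzmann midpoint at
−28 mV and slope 7 mV; inactivation is a
falling Boltzmann whose midpoint is expressed through the reference
parameterization's `th_inf`: V½(h) = th_inf + 14.5 mV, so baseline
th_inf = −49.5 puts the midpoint at −35 mV and the best-fit th_inf = −59
moves it to −44.5 mV. The +14.5 mV offset is this package's resolution of
an ambiguity: the reference reports the best fit as th_inf = −59 while
plotting the midpoint moving −35 → −44.5 mV, without stating the mapping.
`sh` is a common depolarizing shift of both midpoints. Boltzmann slopes
(km = 7, kh = 6.5) and gate time constants are standard fast-spiking
constants chosen here and never published by the source — all
slope-dependent quantities (notably the window-current change) are
regression-locked to this package's numeric oracle rather than asserted
against printed approximate percentages.

The window current is quantified as ∫ min(m_inf, h_inf) dV over −100…+20 mV
by the trapezoid rule ("area under the curves" is not given as a formula in
the source). With the adopted slopes, the −35 → −44.5 mV inactivation shift
reduces the window area by 44.7% (the source prints ~30–33%; the figure is
slope-dependent).

Integration is fixed-step RK4 (dt = 0.01 ms; features converge to < 1%
under step halving) with a 200 ms settling period before a 1 s current
step. The stimulus amplitude (1.6 µA/cm²) is the smallest value on a
0.8 µA/cm² grid giving repetitive (≥ 5 Hz) baseline firing, frozen
thereafter; the source's injection protocol is unpublished. Spikes are
upward 0 mV crossings with a 2 ms lockout; the firing rate counts spikes in
the second half of the step (excluding the onset transient), and width and
amplitude are computed on the mean spike waveform **with the same
operators used for experimental waveforms**, so model/experiment factor
ratios share semantics. Strongly perturbed parameter sets that stop spiking
(e.g. the large common depolarizing shift combined with a tripled rectifier
conductance) are reported as failed rows and excluded from the fit rather
than silently dropped.

Best fit minimizes the uniformly weighted sum of squared differences to the
experimental triple (0.41, 0.71, 0.46); ties break toward fewer perturbed
parameters, then smaller total |Δ|. Weighting is configurable because the
amplitude factor is the acknowledged worst-fit dimension. In this
single-compartment model the winning row is the pure inactivation shift
(th_inf = −60, factors ≈ 0.50/0.74/0.67), consistent with the reference's
conclusion that a single inactivation-shift parameter explains the data
best; the exact winning magnitude differs because the compartmental
reduction changes the rate–current curve.

## Group statistics and report (`ca1lamina.reporting`)

Two-group comparisons are two-sided Mann-Whitney tests with the cell as the
unit of analysis (animal-level nesting is reported but not modeled,
matching the source's cell-level nonparametric tests); the velocity dose
analysis is an ordinary one-way ANOVA across control / ~190 / ~260 rad/s.
Summaries are mean ± SEM. α = 0.05 throughout except the per-frequency PSD
masks at 0.01. The run report assembles all stage outputs into JSON +
Markdown with explicit gaps for missing stages and provenance (seeds,
config hash, package version; no timestamps, so reruns are byte-identical).

## Problem sizes

The cohort analysis simulates 8 + 9 animals at 120 s and 2 kHz with 13
units per animal; estimator-validation tests use up to 600 s single units
(≥ 10⁵ spikes) for the ±0.003 MVL oracle, 5×10⁵ direct von Mises draws for
the analytic checks, twenty 100 s backgrounds for detector false-positive
calibration, and 1–2 s integrations for the cell model. These sizes were
chosen so each check's sampling error sits well inside its assertion
tolerance.

## Numerical choices and edge cases

- ACG bins are half-open `(ℓ−0.5, ℓ+0.5]` ms; an all-zero ACG (no pair
  within 50 ms) yields an undefined, flagged first moment.
- MVL of an empty phase pool raises; bands with no in-window spikes are NaN
  in profiles and skipped in group tests.
- k-means is seed-fixed and order-invariant (10 k-means++ restarts).
- Degenerate ANOVA input (all values identical) returns a flagged NaN
  rather than a spurious statistic.
- Integration failure (|V| > 200 mV) raises with diagnostics instead of
  returning a corrupt trace.
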