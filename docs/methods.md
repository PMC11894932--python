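# Methods

This note describes the models and procedures implemented in `phaseconn`,
the assumptions they carry, the defaults and why they were chosen, and the
limits of what the synthetic-data tests establish.

## The analysis problem

Resting-state EEG is non-autonomous: the oscillatory modes it contains
(theta near 4–7 Hz, alpha near 8–12 Hz, both lower and broader in young
children) drift in frequency and amplitude over seconds. Time-averaged,
amplitude-weighted connectivity measures blur such dynamics and are easily
corrupted by movement artefacts, which dominate amplitude but barely touch
phase. `phaseconn` therefore works with *instantaneous phase* throughout:
functional connectivity is the consistency of a phase difference over time,
and effective (directed) connectivity is the inferred dependence of one
oscillator's phase velocity on another's phase. The merged theta–alpha band
3.5–12 Hz is the default analysis interval; in paediatric EEG the two bands
are not separable by fixed limits, so they are treated as one interval
(configurable).

## Time–frequency representation

The continuous wavelet transform uses the Morlet mother wavelet

    Psi(s, t) = pi^(-1/4) (e^(2*pi*i*wc*t/s) − e^(−(2*pi*wc)^2/2)) e^(−t²/(2 s²)),

with scale–frequency map `f = wc/s`. The resolution parameter `wc` counts
oscillation cycles per Gaussian standard deviation; the default `wc = 4`
matches the convention of the wavelet toolboxes used for this kind of EEG
analysis, where the "frequency resolution" setting is this cycle count.
Frequencies are log-spaced (24 voices per octave by default, ≤1% spacing
over 3.5–12 Hz). The transform is evaluated by frequency-domain
multiplication and is tested for 1e−10 agreement against direct quadrature
of the defining integral.

Normalisation: a unit-amplitude sinusoid at an on-grid frequency produces a
ridge of modulus 1.0. Band-integrated power is *not* signal variance under
this convention; `band_power` applies the closed-form calibration factor
`sqrt(pi)*wc` on a log-frequency axis, which restores Parseval-style
agreement with the variance of band-limited content (verified to 10% in
tests).

Edges are zero-padded and flagged rather than tapered: each row's cone of
influence extends `sqrt(2)` envelope standard deviations (`sqrt(2)*wc/f`
seconds) from either end, and all downstream statistics exclude flagged
cells. Exclusion, unlike tapering, leaves the retained phase estimates
unbiased. Records must hold at least 2 cycles of the lowest analysis
frequency (error) and should hold 30 (warning), the usual guidance for
detecting coupled oscillations.

## Wavelet phase coherence

Time-localised WPC at `(t, f)` is the modulus of the mean unit phasor of
the phase difference over a centred window of 10 complete cycles of `f`
(window `10/f` seconds). The integral is discretised as a mean over the
samples inside the window; windows that leave the record are masked, not
shortened, because shortened windows inflate coherence at the edges. The
estimator is, by construction, exactly invariant to any time-constant
positive rescaling of either signal.

Two estimator facts shape everything downstream:

* **Bias floor.** For phase-independent signals the 10-cycle window holds
  only ~1–3 decorrelation lengths of wavelet-filtered noise, so the
  expected WPC of *unrelated* signals is high (about 0.7 at 11 Hz with
  `wc = 4`). This is not a defect of the implementation but a property of
  short-window phase coherence, and it is the reason the pipeline never
  interprets raw WPC: only the surrogate-subtracted ("effective") value is
  meaningful.
* **Record length does not cure the bias.** The time average of the
  windowed statistic converges to the per-window bias as the record grows;
  only widening the window lowers it. Tests assert both facts.

Band-averaged values are formed by time-averaging each row first, then
averaging rows within 3.5–12 Hz (the order is a convention; it is fixed
and documented here because the two orders differ slightly on masked
grids).

## Global coherence (wavelet mean field)

Per scale, each channel's transform is divided by the root of the grand
mean squared modulus across channels and time; the mean field `r_sigma(t)`
is the channel average of these normalised transforms, and global coherence
is the time-mean of `|r|²` — 1 for complete cross-channel synchrony,
~1/N for N independent channels. An "effective" global coherence subtracts
the same intersubject surrogate construction (composite subjects whose
channels come from distinct real subjects) before band averaging.

## Intersubject surrogates and effective coherence

Genuine inter-probe coherence can only exist within a subject. For a group
of n subjects and a probe pair (p, q), coherence spectra are computed for
all ordered cross pairings (subject i's p against subject j's q, i ≠ j):
n² − n spectra whose per-frequency mean estimates the apparent-coherence
level. That mean is subtracted from each subject's actual spectrum,
negatives are clipped to zero, and the band average gives one nonnegative
scalar per subject and pair. For coupling strengths, whose null values run
systematically higher, the threshold is the 95th percentile of the
surrogate pool (linear interpolation between order statistics — the numpy
default — so the 95th percentile of {1,…,100} is 95.05), with at least 20
null samples recommended. The surrogate statistic for coupling is the
per-cross-pair time-averaged strength; a per-window alternative can be
assembled from the returned per-window series.

## Dynamical Bayesian inference of phase couplings

The bivariate phase model is

    dphi_i/dt = sum_k c_k^(i) Phi_k(phi_A, phi_B) + xi_i,  i ∈ {A, B},

with `Phi` a constant plus sin/cos of `(m phi_A + n phi_B)` for all wave
vectors up to Fourier order 2 (25 base functions per equation; order is
configurable) and white noise with inferred 2×2 covariance. Derivatives are
midpoint-discretised; within each window the Gaussian posterior over the
stacked coefficient vector has the closed form used throughout the
dynamical-inference literature: information matrix
`Xi = Xi_prior + h * kron(E^-1, P^T P)`, right-hand side containing the
`E^-1`-weighted phase increments and the midpoint Jacobian drift term
`−(h/2) Σ ∂Phi_k/∂phi_i`, and noise update `E = (h/N) * res^T res`,
iterated to a joint fixed point.

**Numerical choice — drift-term fallback.** The coefficient/noise fixed
point exists only when the inferred noise is small enough; the drift
correction scales linearly with `E`, so for noise-dominated windows (phase
slips in broadband signals) the joint update diverges. The iteration is
convergence-checked, and windows without a stable fixed point are refitted
with the drift term dropped (a weighted least-squares posterior). Clean
oscillatory data never triggers the fallback; the parameter-recovery tests
run entirely on the full method.

**Windowing and propagation.** Windows are 3 s (≥10 cycles of 3.5 Hz,
10/3.5 ≈ 2.9 cycles per second of window) with unity overlap (no overlap);
a 180 s segment yields 60 fits. Between windows the posterior propagates:
`Sigma_prior = Sigma_post + p² diag(Sigma_post)` with propagation constant
`p = 0.2`. Small `p` pins coefficients to their history (smooth
trajectories); large `p` forgets quickly; `p = None` gives fully
independent windows. Note the direction of this knob: 0 is *maximal*
information transfer, matching the propagation convention of the DBI
literature.

**Phases for inference** come, by default, from a zero-phase Butterworth
bandpass (order 4) over 3.5–12 Hz followed by the analytic-signal argument,
unwrapped; a wavelet-ridge phase is available behind a flag. Unwrapped
phases are subsampled to 40 Hz before inference (≥3× the band top; the
midpoint discretisation error at 40 Hz biases an 11 Hz coupling coefficient
by under 3%, and the cost drops ~6×). Both the rate and the source are
configurable.

**Statistics.** The directional strength is the Euclidean norm of the
cross-terms (base functions involving the source phase) in the target's
equation — constants and self terms excluded, so an uncoupled pair scores
only its noise floor. Because a single anomalous window can dominate a
time-averaged strength, the reported quantity is *coupling time*: the
percentage of windows strictly above the surrogate threshold.

**What same-band inference can see.** A coupling term depending on the
source phase alone modulates the target at the source frequency; when
source and target share a band (e.g. both ~11 Hz), the FM sidebands land
near 0 and twice the band — outside any bandpass — and the coupling is
invisible to band-limited phases. Terms in the phase *difference* modulate
at the slow beat frequency and are recoverable. The coupled-oscillator
demo keeps the source-only `E cos(phi_X + pi/2.5)` form and is analysed on
raw phases; the cohort generator's directed mechanism uses the difference
form `sin(phi_src − phi_tgt + pi/2.5)` for exactly this reason.

## Group statistics

* `rank_sum` — two-sided Wilcoxon rank-sum; exact when the smaller group
  has ≤10 observations and there are no ties, otherwise the normal
  approximation with midrank tie correction. At the study sizes (13 vs 9)
  the exact test's attained size at nominal 0.05 is ≈0.043, a discreteness
  effect worth remembering when reading calibration numbers.
* `friedman_repeats` / `kruskal_wallis_per_subject` — consistency of a
  subject's values across repeated segments; complete blocks required
  (incomplete blocks dropped with a warning).
* `shuffled_segment_test` — per shuffle, one uniformly random segment per
  subject, then a rank-sum between groups; reports the percentage of
  shuffles significant at P < 0.05 (1000 shuffles by default, seeded and
  bit-reproducible). Guards against segment timing acting as a confound.
* `cohens_d` — pooled-variance convention (`n − 1` weights); the Hedges-g
  small-sample correction is documented in tests but not applied.
* `sensitivity_mdes` — smallest detectable Cohen's d via noncentral-t root
  finding; for the Wilcoxon test the sample sizes are first multiplied by
  an asymptotic-relative-efficiency factor. The default parent convention
  is the distribution-free minimum (0.864) — the default of the standard
  power-analysis software for this test; normal (3/π), logistic, Laplace
  and uniform parents are selectable. For 13 vs 9 at two-sided alpha 0.05
  and power 0.80 the default gives d = 1.387 (normal parent: 1.311).
  Power 0.80 is the conventional assumption and is configurable.
* `age_regression` — OLS slope, Pearson r, two-sided P; constant inputs
  return r = 0, P = 1 by convention.
* A Bonferroni-adjusted threshold (0.05/4 = 0.0125 for the four frontal
  pairs) is a reporting option, not applied by default.

## Synthetic data: what it emulates, what it does not

`generate_two_mode_pair` reproduces the two-mode demonstration design:
theta at 5.5 Hz and alpha at 11 Hz, each with slow sinusoidal frequency
drift (±0.4 / ±0.5 Hz, periods of tens of seconds), unit amplitudes,
additive white Gaussian noise with SD 0.5, and an alpha mode shared between
channels only after a configurable onset. The drift laws and noise level
are this package's defaults (documented, overridable), chosen as realistic
desk-scale stand-ins.

`generate_coupled_oscillators` integrates the unidirectional pair
(`omega_X = 2π·5`, `omega_P = 2π·8` rad/s by default, coupling
`E cos(phi_X + π/2.5)`, noise 0.1 rad/√s) by Euler–Maruyama at the signal
sampling rate — deliberately the same discretisation the inference stage
assumes.

`generate_cohort` builds two-group multichannel cohorts. Each channel mixes
a theta mode, an alpha mode and white noise; channels of designated pairs
share an alpha phase (weight `w`, with the independent remainder weighted
`sqrt(1 − w²)` so that variance — and hence spectral power — carries no
group information), or are phase-driven through the difference coupling.
Group 2's structure is scaled by `group_effect`. Per-subject and
per-channel mode centre frequencies are randomised (alpha 11 ± 0.5 Hz,
theta 5.5 ± 0.3 Hz, randomised drift period and phase): individual alpha
peaks differ by about this much in children, and without that variability
cross-subject "apparent" coherence would sit near 1 and surrogate
subtraction would be meaningless.

What passing tests on these cohorts shows: the estimators are correctly
implemented, calibrated under the null, and sensitive to phase-structure
differences at realistic sizes. What they do not show: robustness to real
artefact morphology (blinks, EMG, electrode pops), volume conduction,
non-Gaussian broadband backgrounds, or 1/f spectral shape — none of which
the generators attempt to mimic.

## Pipeline conventions

Preprocessing defaults (the clinical recipe is study-specific, so these
are explicit stand-ins): per-channel mean removal, zero-phase high-pass
below 0.5 Hz, optional 50/60 Hz notch; every step logged; no
re-referencing. Segmentation supports explicit (video-selected) starts,
sequential non-overlapping segments (five 3-minute segments by default),
and the central 3 minutes. Recordings are 10–20-labelled matrices at 256
or 500 Hz (other rates warn); EDF is read via `mne`, delimited matrices
round-trip losslessly at 17 significant digits, and MATLAB containers are
read through a thin converter. Cohorts are written as per-subject
delimited matrices plus a metadata CSV (no EDF writer is bundled).
`run_pipeline` chains the stages, emits tidy CSV tables, per-group
heatmap matrices (symmetric for WPC, directional for coupling time),
group-statistics JSON, and a manifest with the config hash and seed;
given a seed the whole run is bit-reproducible.

## Problem sizes in the shipped tests

The test suite runs every estimator at reduced sizes chosen so the science,
not the arithmetic, is what is being checked: 12–32 s cohort segments at
32–64 Hz with 8–12 voices per octave, 120 s oscillator records, and the
full 400 s two-mode record for the coherence-contrast check. The null
calibration uses 2000 replicate cohorts (13 vs 9) with the per-subject
band-averaged coherence as the statistic (exchangeability makes surrogate
subtraction unnecessary for a size check). Package defaults remain at
study scale: 180 s segments, 256 Hz, 24 voices per octave, 1000 shuffles.

## Known limitations

* Time-localised WPC carries a large finite-window bias; only effective
  (surrogate-subtracted) values are interpretable, and weak genuine
  coherence close to the bias floor is hard to detect at short segment
  lengths.
* The DBI noise model is white and Gaussian; windows dominated by phase
  slips fall back to the drift-free fit, and strongly non-stationary noise
  within a 3 s window violates the model either way.
* Same-band directed inference cannot see source-only couplings between
  oscillators at the same frequency (sideband argument above); absence of
  inferred coupling is not absence of interaction.
* Cross-frequency coupling (different bands per probe) is out of scope.
* The classifier stage of a full biomarker study is out of scope; the
  pipeline's CSV exports are the feature-table boundary.
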