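# Methods

This note documents the models, defaults, and numerical choices behind
`stimtrack`, and what the synthetic-data tests do and do not establish
about real recordings.

## The coherence model

The quantity of interest is the phase consistency between a stimulus
time series (the IVC motion energy of a video) and each EEG channel,
estimated independently in overlapping log-spaced frequency bands.

* **Filter bank.** Band centers are `f = 2ⁿ` for `n = −1, −0.5, …, 4`
  (11 bands, 0.5–16 Hz); each band spans `(0.8 f, 1.25 f)`. Adjacent
  half-octave bands overlap (1.25 > 0.8·√2), so neighboring bins share
  signal — relevant when interpreting cluster extents across bins.
* **Filters.** Butterworth band-pass of order 3 per pass, applied
  forward and reverse (`sosfiltfilt`), so the effective order is 6 and
  the phase response is exactly zero. The order is a design choice:
  ripple-free passbands with usable roll-off at half-octave spacing.
* **Analytic signal.** Envelope and instantaneous phase come from the
  FFT-based Hilbert transform of the filtered signal.
* **Coherence.** `Coh = |Σ w e^{iθ} P_C P_V| / Σ w P_C P_V` with optional
  per-sample weights `w`. Weights default to 1; when an artifact mask is
  present its taper weights are used, so zero-filled stretches do not
  masquerade as (zero-phase-difference) signal. Coherence is invariant
  to rescaling either signal and to any constant time lag of a
  narrowband pair, which is why the synthetic generator can couple with
  a fixed physiological-looking lag (100 ms default) without affecting
  ground-truth coherence.

## Surrogate null and z-scoring

The null hypothesis — no temporal relation between stimulus and EEG — is
simulated by circularly rotating the stimulus to a random onset
(uniform over `[min_shift, T − min_shift]`; `min_shift` defaults to
10 s, keeping surrogates decorrelated from the true alignment).
Rotation preserves both marginal spectra. Per cell, empirical coherence
is z-scored against the mean and SD (n−1 denominator) of 100 surrogate
values.

Numerical implementation: the coherence sums for *all* rotations are
circular cross-correlations, evaluated at once via FFTs (zero-padded to
an FFT-friendly length ≥ 2T, with the wrapped lag folded back, so
awkward prime-length spans stay fast). The rotation is applied to the
stimulus's analytic-band representation rather than by re-filtering the
rotated raw signal; the two differ only through filter edge transients
(median |Δ| ≈ 5 × 10⁻⁴ in coherence units on 60 s test signals), and a
`refilter=True` path implements the literal procedure for
cross-checking. The empirical map is the zero-offset evaluation of the
same estimator, so empirical and surrogate values are exchangeable
under the null — the property that makes the z-scores calibrated
(pooled null z-scores: |mean| < 0.1, |SD − 1| < 0.15 at the 10-minute,
32-channel, 100-surrogate scale).

The pipeline trims each analysis span to the nearest 5-smooth length
(dropping at most a fraction of a percent of samples at the end of the
span) for the same FFT reason; `trim_to_fast_len=False` disables this.

## Cluster-based permutation tests

Cell-wise *t* statistics (paired/one-sample for dependent designs,
pooled-variance two-sample for independent) are thresholded at the
two-tailed α = 0.05 critical value of the *t* distribution at the
design's df. Supra-threshold cells form clusters when they share a sign
and are connected — same channel and adjacent frequency bins, or
neighboring channels (Euclidean distance ≤ `max_dist`) and the same
bin. Clusters spanning fewer than 2 distinct channels are discarded.
The cluster statistic is the **cell count** (an option switches to
summed |t|). The null distribution records the maximum cluster size per
permutation: sign flips of per-subject differences (dependent) or
group-label shuffles (independent).

When the requested `k` covers the whole permutation group (2ⁿ sign
flips, or all label assignments), the test enumerates it and p-values
are exact (`b / n_perms`, identity included, so p is never 0).
Otherwise p = (b + 1)/(k + 1), the standard validity-preserving
Monte-Carlo estimate; the identity permutation is always included in
the sample. The expertise interaction is tested as a
difference-of-differences: per-subject (stimulus A − stimulus B) maps,
compared between groups with the independent design. Group or stimulus
main effects cancel in this contrast by construction; the test suite
verifies that a group main effect alone does not produce spurious
interactions.

The empirical-versus-surrogate within-subject contrast is implemented
as a paired *t* of each subject's empirical map against that subject's
mean surrogate map — the slope test of a two-level regression, which is
the natural reading of a dependent-samples regression with one
empirical and one baseline level per subject.

## ROI statistics

Z-maps are averaged over an a-priori channel set and over the bins whose
centers fall in the frequency range, endpoints inclusive: the default
0.5–2 Hz range selects the five bins centered at 0.5, 0.707, 1, 1.414,
and 2 Hz. The contrast report uses Welch *t* tests (two-sample between
groups; one-sample on paired differences within groups; one-sample
vs 0 for above-chance tests), each with Cohen's *d* and a large-sample
95% CI. ANOVA, mixed-effects, and Bayesian re-analyses are deliberately
out of scope; the report's `extras` dict is the hook for bolting those
on from external packages.

## Spectral parameterization

Welch spectra (64-sample segments, 32-sample overlap, Hanning window,
per-segment linear detrend — 2.13 s / 1.07 s at a 30 Hz video rate) are
fit up to 15 Hz in log₁₀-power space as a knee-aperiodic curve
`b − log₁₀(k + f^χ)` plus Gaussian peaks. Peaks are seeded iteratively
from the flattened residual while its maximum exceeds 2 × the residual
SD, with widths constrained to 1–8 Hz (bandwidth = 2 Gaussian SD).
Because the initial aperiodic fit is biased upward wherever a peak
sits, the implementation alternates a joint Gaussian refit with a plain
aperiodic refit on the peak-removed spectrum (6 inner iterations, up to
3 pruning rounds); peaks hugging a range edge (< 1 SD away), peaks
overlapping a taller peak (centers closer than 0.75 of their summed
SDs), and peaks falling below the detection threshold after refinement
are dropped and the survivors refit. On constructed spectra this
recovers a 4.4 Hz, 0.29-height, 1.6 Hz-bandwidth peak to within
0.01 Hz / 0.01 log-units; the test tolerances (±0.3 Hz, ±0.05) leave
room for grid effects at other settings.

## The synthetic generator

The generator is the package's testbed: every statistical property is
validated against data whose ground truth is known exactly.

* **Motion traces** are renewal burst trains — gamma-distributed
  inter-burst intervals (shape 3, mean 1/`burst_rate_hz`; default
  2.2 Hz, the rate of short movement units in signing) with lognormal
  burst amplitudes — convolved with a causal exponential kernel
  (τ = 60 ms). The exponential kernel is deliberate: it gives the trace
  a Lorentzian `1/(k + f²)` spectrum, which lies exactly in the family
  the knee-aperiodic model represents, so an unmanipulated trace
  parameterizes as peak-free. (A Gaussian smoothing kernel, by
  contrast, has a super-exponential spectral roll-off that no
  `k + f^χ` curve can follow and produces spurious "peaks" that are
  really background misfit.)
* **Periodic component.** A dance-like theta peak is injected as a weak
  sinusoid whose instantaneous frequency wanders (Gaussian sd 0.55 Hz,
  low-passed at 0.2 Hz), broadening the spectral line to a fittable
  1–2 Hz bandwidth. Its amplitude is calibrated in closed form against
  the trace's own background power so the fitted peak height
  approximates the requested log₁₀ value; the default "dance" stimulus
  carries a (4.4 Hz, 0.29) peak and the "sign" stimulus none.
* **Videos** render a Gaussian blob (SD 2 px) whose per-frame sub-pixel
  displacement is proportional to √IVC; for steps ≤ 0.4 px the
  frame-difference energy is quadratic in displacement, so the
  rendered video's IVC reproduces the target trace with r > 0.99.
* **EEG** is per-channel 1/f^χ noise (χ = 1 default) synthesized by FFT
  spectral shaping. Coupling adds, at the target channels, the
  band-pass-filtered and lag-shifted stimulus scaled to
  `coupling_strength` × the channel's own background RMS in that band —
  amplitude-and-phase locking rather than literal evoked responses,
  because the coherence statistic is lag-invariant and this keeps the
  ground truth analytically controllable.
* **Triggers** occur every 30 frames; EEG-side times are stretched by a
  configurable clock drift (ppm) plus bounded uniform jitter. Cohort
  defaults: 50 ppm and 1 ms.
* **Cohorts** share one trace per stimulus across subjects (everyone
  "watches the same videos"); per-subject coupling variability is a
  lognormal multiplier (log-SD 0.2) shared across a subject's
  recordings. The sensor layout is a built-in 32-position spherical
  approximation of a 10-20 montage with named frontal / occipital /
  mastoid groups standing in for a priori ROIs of a high-density net.

What the synthetic data does *not* emulate: volume conduction and
channel covariance, blinks and muscle artifacts, evoked transients,
non-stationary coupling, or biomechanically realistic kinematics.
Passing tests therefore establish the estimator's statistical
properties (calibration, error control, power under known coupling),
not robustness to every physiological nuisance in real EEG.

## Problem sizes for the calibration experiments

The Monte-Carlo validations run at scales chosen for a single CPU while
keeping every estimate's sampling error well inside its acceptance
band: null z-score calibration at the full 10 min × 32 channel ×
100-surrogate scale; family-wise error with 200 repetitions of a
10-subject, 20-channel, 60 s (100 Hz, 40 surrogates, k = 500) null
pipeline; interaction recovery/specificity with 20 cohorts per
condition of 2 × 10 subjects × 2 stimuli at 45 s per recording
(30 surrogates, k = 1000). The acceptance script repeats the same
computations at 100 repetitions / 10 cohorts per condition.

## Degenerate inputs and errors

Constant traces cannot be normalized; all-zero weight products make
coherence undefined; zero surrogate spread blocks z-scoring (the check
uses a relative 1e-12 tolerance, since identical floating-point
surrogates need not have a bitwise-zero SD); masking is idempotent
because the recording maintains `data = clean × valid_mask` and
re-masking applies only the mask ratio. All such conditions raise typed
exceptions (`ParameterError`, `InputError`, `DegenerateInputError`,
`FitError`) rather than propagating NaNs.

## Known limitations

* Coherence is undirected; no latency or directionality estimates.
* The paired-contrast reading of the within-subject
  empirical-vs-surrogate test is one of two plausible formulations (the
  other treats all 100 surrogates as regression observations); both are
  valid tests, and the choice only affects within-subject power.
* The cluster statistic (cell count) ignores effect magnitude above
  threshold; the `sum_t` option is provided for sensitivity analyses.
* Sampled permutations are drawn with replacement from the group; for
  very small samples the exact enumeration path engages automatically.
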