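# Methods

`stdtlab` simulates and analyzes a somatosensory temporal discrimination
experiment end to end: synthetic observers produce behavior, a calibration
chain turns that behavior into an individually calibrated stimulus design, a
matching task decouples percept from report, synthetic EEG carries a
percept-dependent ERP modulation, and a mass-univariate pipeline recovers
that modulation with family-wise error control. Everything below is the
package's own account of the models, their parameters, and the choices made
where the design was open.

## Observer model

An observer is a two-parameter logistic psychometric function for "felt as
two" responses,

    p(ISI) = lapse/2 + (1 - lapse) / (1 + exp(-(ISI - T50)/s)),

with threshold `T50` (the somatosensory temporal discrimination threshold,
STDT) and scale `s`, both in ms. The slope at threshold is `(1 - lapse)/(4s)`
per ms; `T01 = T50 - s ln 99` and `T99 = T50 + s ln 99`, so
`T99 - T50 = T50 - T01` holds by construction. The lapse term defaults to 0
(the pure two-parameter model); it exists solely to generate the imperfect
asymptotes that can drive a fitted T01 negative. Single-pulse detection is a
hard threshold in mA, optionally softened by Gaussian intensity noise; at
zero noise the boundary is inclusive (intensity equal to threshold is felt),
with a 1e-9 mA tolerance so that staircase arithmetic on decimal steps is not
derailed by float accumulation.

Cohorts draw `T50` log-normally with median 30.38 ms and mean 45.19 ms, which
fixes the log-space SD at `sqrt(2 ln(mean/median)) ≈ 0.89`; the population SD
(≈35 ms) is then an emergent property, approximately rather than exactly
matched. The logistic scale is log-normal around a median of 8.28 ms — the
value implied by the group-mean T01/T99 span, `(78.56 - 2.45)/(2 ln 99)` —
with log-SD 0.35 chosen to produce visibly heterogeneous slopes. Detection
thresholds are normal with mean 2.425 mA and SD 0.46 mA (half of the
4.85 ± 0.92 mA stimulation intensity, which is twice threshold), truncated at
0.5 mA.

## Calibration chain

*Intensity staircase.* From 1 mA upward in 0.1 mA steps until the pulse is
felt; the step then halves and the direction reverses, for three ascending
and three descending progressions (steps 0.1, 0.05, 0.025, 0.0125, 0.00625,
0.003125 mA). Each progression ends at its reversal value. How the final
threshold is read off a staircase is not standardized; we use the arithmetic
mean of the six reversal values, which is common practice and makes the
procedure exactly testable: deterministic observers yield hand-computable
traces, and a brute-force sweep over thresholds in [1.2, 5] mA bounds the
estimate error at 0.05 mA (measured maximum ≈ 0.015 mA). Stimulation
intensity is twice the estimate.

*STDT staircase.* Three ascending ISI series (from 2 ms in 5 ms steps,
stopping at the first "two" percept) interleaved with three descending series
(from 120 ms, stopping at the first "one"); the initial STDT estimate is the
mean of the six stopping points. Starting points and step size are our
defaults; they bracket the plausible STDT range and keep the estimate within
one step of the true threshold for deterministic observers.

*Psychometric session and fit.* 15 ISIs linearly spaced with 2 ms as the
lowest value and the initial STDT as the 8th (median) value, 20 repetitions
each (300 trials). The logistic is fitted by binomial maximum likelihood
(Nelder-Mead from a moment-based start, then a BFGS polish; fixed tolerances
make the fit deterministic). The reported mean squared error between observed
and fitted per-ISI proportions is a post-fit diagnostic, not the fitting
criterion. Noiseless data are recovered to optimizer tolerance; across 500
simulated sessions at (T50 = 40, s = 8) the median threshold error is well
below 2 ms and the recovery RMSE shrinks as repetitions double.

*Main-experiment design.* Ten equally spaced ISI levels span T01..T99. When
the fitted T01 falls below the 1 ms hardware floor, the whole span shifts
symmetrically toward the STDT: the minimum becomes 1 ms and the maximum is
reduced by the same amount `Δ = 1 - T01`, so the STDT remains the exact
midpoint of the levels in both branches. A degenerate shifted design
(top ≤ floor) is rejected as an exclusion; note that with the midpoint
identity this coincides with `T50 ≤ floor`, which the precondition already
rejects — the dedicated guard is defensive. Trials per 200-trial run follow
a normal-density profile over levels anchored at the published counts
(8 at levels 1/10, 32 at levels 5/6). No discretization of a normalized
normal density reaches both anchors simultaneously, so the anchors are
treated as constraints: the Gaussian through them (center 5.5, σ² =
20/ln 16) distributes the remaining 120 trials over levels 2–4/7–9 by
largest-remainder rounding, giving the canonical allocation
[8, 13, 20, 27, 32, 32, 27, 20, 13, 8].

## Matching task

On each trial the cue (white = "two", dark = "one") is drawn 50/50
independently of the ISI, and the participant reports whether the percept
matches the cue: (two, white) and (one, dark) are matches, the other two
cells mismatches. Because the cue is independent of the percept, percept and
report are independent by construction — a single flip of either argument
inverts the truth value, and the marginal match probability is exactly 0.5.
The default reporter is error-free (participants passed a ≥90%-accuracy
screen); a symmetric report-error rate is available for robustness studies.
Reaction times are log-normal with identical parameters for both percepts
(median ≈ 0.31 s, log-SD 0.15), reflecting the absence of evidence for an RT
difference; missed trials occur at rate 0.021, carry no report and no RT, and
are excluded from every analysis. Sessions comprise 7 (or 6) runs of 200
trials; ISI levels are exactly counterbalanced per run, response sides
counterbalanced, intertrial intervals uniform in 0.7–1.3 s.

Near-threshold ("STDT") trials are, per run, the trials of the level whose
ISI is closest to that run's fitted inflection point, ties broken toward the
lower level; run fits that are degenerate (for instance a run in which one
response never occurs) fall back to the calibration fit.

## Bayes factors

The reaction-time test is the JZS one-sample Bayes factor on paired
differences: a Cauchy(0, r) prior on the standardized effect with
`r = sqrt(2)/2` (the common default; the scale is a parameter), evaluated by
adaptive quadrature over the equivalent g-prior mixture. The test suite
checks it to 0.1% against an independent dense-grid integral of the
noncentral-t likelihood over the Cauchy prior, and against `pingouin`'s
implementation.

The percept/report association test is the joint-multinomial
Dirichlet-multinomial Bayes factor for a contingency table: under the full
model the cell probabilities have a Dirichlet prior with unit concentration
per cell; under independence the row and column margins have Dirichlet priors
with the collapsed concentrations. Both marginal likelihoods are ratios of
Dirichlet normalizers, so BF01 is closed-form; the test suite checks it
against a 10^6-draw Monte-Carlo estimate of both marginal likelihoods.
Evidence labels follow Kass & Raftery with left-closed bins at 1, 3, 20,
and 150 on the oriented factor max(BF10, BF01).

## Synthetic EEG

Sixty-four channels on the extended 10–20 biosemi layout (plus vEOG/hEOG),
projected azimuthally onto the unit disk. Four separable Gaussian
(space × time) components model the somatosensory evoked response: P50
(50 ms, CP4, +2 µV), N140 (120 ms, C6, −4 µV — it peaks early in this
paradigm), P170 (170 ms, FC2, +3 µV), and P300 (300 ms, CPz, +5 µV,
temporal σ 45 ms). Only the P170 is percept-dependent: "felt as two" trials
receive `amp_one + δ` with default δ = 2.5 µV, which places the maximal
condition difference at 170 ms inside the 129–178 ms analysis window.
Component widths are not empirically constrained; the defaults (temporal σ
12–45 ms, spatial σ 0.20–0.35 of the head radius) are explicit tuning
choices.

Noise is 1/f (exponent 1) plus a 10 Hz alpha bump, normalized per channel
and spatially mixed through the Cholesky factor of a squared-exponential
channel correlation (length scale 0.6). The single-trial channel noise SD
defaults to 6 µV, intended as the residual in the 0.01–40 Hz analysis band;
with the desk-scale session (~32 trials per condition) this yields a
subject-contrast standard error of ≈1.5 µV, consistent with the group-level
simulation default of 1.2 µV (≈50 trials per condition). Blinks are
stereotyped 250 ms squared-Hann deflections, 300 µV on vEOG, propagated to
the scalp with an exponential front-to-back decay (length 0.2 in projected
coordinates).

What the generator does *not* emulate: between-subject amplitude or latency
differences (all subjects share the component fields; a gain-heterogeneity
parameter exists but defaults to 0), latency jitter, non-stationary noise,
muscle or electrode artifacts beyond the synthetic transients used in tests,
and any dependence of EEG on the cue or report. Passing tests therefore
establish that the analysis chain is correct and calibrated under this
idealized forward model — not that it would have equal power on real
recordings.

## Preprocessing

Pipeline order: high-pass 0.01 Hz → notch 48–52 Hz → downsample to 512 Hz →
common-average reference (EOG excluded) → blink removal → epoch −100..600 ms
→ artifact rejection and bad-channel interpolation → low-pass 40 Hz (applied
to epochs) → baseline correction (−100..0 ms). Filters are zero-phase
Butterworth second-order sections with fixed orders (band-stop 4, low-pass
4). The 0.01 Hz high-pass is *not* implemented as a direct IIR: at kHz rates
its poles sit within ~1e-5 of z = 1, which is numerically ill-conditioned and
has transients longer than most recordings. Instead the sub-cutoff drift is
estimated on a block-mean-decimated copy (≈2 Hz) with an order-2 zero-phase
low-pass and subtracted; for records shorter than three cutoff periods
(300 s) the drift estimate degenerates, correctly, to the mean.

Blink removal detects vEOG peaks above 100 µV with a 0.5 s refractory
period, averages the scalp pattern at the peaks into a template topography,
and removes that single spatial component by rank-1 projection (at least 3
blinks are required for a stable template; otherwise the data pass through
with a warning). The projection removes the blink subspace entirely; its
leakage into the P170 is bounded in tests at the effect's peak channel and
latency (<5% amplitude change).

Epochs take all integer sample indices n with `tmin·fs ≤ n ≤ tmax·fs` —
359 samples at 512 Hz. Artifact screening replaces visual inspection with a
deterministic peak-to-peak criterion (150 µV per channel and trial);
channels bad in more than 20% of trials are interpolated everywhere by
inverse-distance weighting over their six nearest neighbors, remaining bad
trials are dropped, and more than half the channels bad aborts the run.

Scalp volumes are linear (Delaunay barycentric) interpolations of the 64
channel values onto a 32 × 32 grid over the unit-disk bounding box, per time
sample: 32 × 32 × 359 values per trial, with cells outside the electrode
convex hull masked (542 of 1024 cells are inside for this layout). Linear
interpolation reproduces electrode values exactly and is exact for affine
fields, both of which are tested.

## Group statistics

First level: regression of per-trial voxel values on the two percept
indicators; the contrast `β_two − β_one` equals the difference of condition
means exactly, so the pipeline computes condition means in channel space and
interpolates the contrast once per subject (the per-trial-volume route is
equivalent by linearity and is tested against it). Second level: per voxel,
`y = β₀ + β₁(c − mean(c)) + ε` across subjects with the participant STDT as
covariate `c`; the one-tailed t for β₀ > 0 (direction "two" > "one") has
n − 2 degrees of freedom. Clusters are face-connected (6-connectivity)
components of the map thresholded at one-tailed p < 0.001.

Family-wise error is controlled by a max-statistic sign-flip permutation
scheme — a deliberate methodological substitution for random-field-theory
correction, chosen because it is assumption-light and its error rate can be
verified by simulation. Subject contrasts are residualized against the
centered covariates, residuals are sign-flipped, and the model is refit per
permutation; the null distributions of the maximum cluster extent and
maximum peak t give `p_FWE = (1 + #{null ≥ observed})/(1 + n_perm)`. The
permutation pass runs in float32 on squared t-ratios (only the
supra-threshold mask and the maximum are needed), which an identity-flip
test pins to the float64 observed map. Sub-analyses: a median split of the
cohort at STDT 30 ms with independent inference per subgroup, and a variant
adding a run-drift covariate (the SD of the selected ISI level across runs).

Calibration of the procedure is itself simulated: under the global null
(δ = 0) the family-wise false-positive rate over 200 simulated 12-subject
experiments at 200 permutations is ≤ 0.065 (measured 0.03–0.05), and with
the default δ = 2.5 µV a significant fronto-central cluster overlapping
129–178 ms is recovered in ≥ 80% of 50 experiments (measured 0.84). These
simulations generate subject contrast volumes directly (effect field plus
trial-averaged noise), which is distribution-equivalent to simulating every
trial and averaging, and run covariate-free; the main analysis keeps the
STDT covariate.

## Problem sizes and defaults

The default experiment profile is desk-scale: 12 subjects, 2 runs of 200
trials each, 200 permutations — a full run takes a few seconds and the
complete validation suite a few minutes on one CPU, while preserving the
per-run structure (10 levels, normal allocation) of the full design. The
cohort-level behavioral study uses the full 34-observer, 7-run configuration.
Sessions at full scale yield ~185 near-threshold trials per subject, matching
the scale of real recordings.

## Known limitations

- The exact reading of several procedural details (staircase threshold
  read-out, STDT staircase step sizes, the discretization behind the trial
  allocation, the fitting criterion of the logistic) is not recoverable from
  the experiment description; each is pinned to a documented convention
  above and exposed as configuration.
- Permutation FWE is a stand-in for random-field-theory correction; cluster
  p-values agree in calibration but not numerically with parametric values.
- The EDF writer is absent from the I/O layer (reading EDF is supported);
  continuous synthetic data are exchanged in memory or as HDF5 containers.
- The blink model is rank-1 by construction, so the template projection is
  near-ideal here; real blink fields are only approximately rank-1.
- Grid geometry (32 × 32 over the unit-disk bounding box, convex-hull mask)
  is config-pinned; other scalp-space conventions would change cluster
  extents but not the inference logic.
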