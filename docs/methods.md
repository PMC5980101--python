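# Methods

This note documents the models, conventions and numerical choices behind
`pheegmark`, and what the synthetic experiments do and do not establish.

## Band power

The nine sub-bands are fixed half-open intervals [f_low, f_high):
Total 0–250 Hz, lDelta 0.1–1.5, Delta 1–4, Theta 4–8, Alpha 8–12,
Beta 12–30, Gamma 30–55, High 70–170, vHigh 190–250 Hz. lDelta and Delta
deliberately overlap (1–1.5 Hz); no disjointness is enforced. Band power
per 250 ms step is the integral of a rectangular-window periodogram
(one-sided PSD, `detrend=False`) over the band's bins. With this
estimator the Total power of a window equals its mean squared amplitude
(Parseval), which the tests verify against a brute-force variance
oracle. Absolute (not relative) power is reported; windowing/tapering
refinements are out of scope. The time axis always has
`floor(duration/step)` points — a one-hour record at 250 ms steps gives
14 400 samples.

## Synthetic generator

Each band-power curve is generated as

    y(t) = baseline_b · offset_{s,b} + slope_{s,d,b} · (t − t_inj)₊ + ε(t) + spikes,

with t in minutes after the injection (minute 9 of the record).
Defaults reproduce the target study design: 3 strains × 10 animals × 5
channels × 8 days, 9 bands, 250 ms steps, one hour per record.

* **Baselines** (power units): Total 100, lDelta 50, Delta 30, Theta 15,
  Alpha 8, Beta 4, Gamma 2, High 1, vHigh 0.5 — strictly decreasing over
  lDelta > Delta > Theta > Alpha > Beta, as in real rodent spectra.
* **Noise**: AR(1) with coefficient 0.9 on the sampling grid. The
  stationary standard deviation is `noise_sd × baseline × offset`
  (default `noise_sd = 0.1`, i.e. 10% of the curve's level). A relative
  rather than absolute sd was chosen because baselines span two orders
  of magnitude; an absolute sd would drown the high bands and leave the
  low bands noiseless. The AR(1) persistence plus sparse positive
  exponential spikes (probability 0.002/sample, mean 3 noise-sd) are
  exactly the disturbances a median filter targets.
* **Outliers**: each curve is independently replaced, with probability
  `outlier_curve_rate` (default 0.02), by the same curve multiplied by a
  factor drawn from {3, 5} — the whole-curve level shifts a functional
  boxplot flags. Ground truth records the post-factor slope/intercept
  and the outlier labels.
* **Floor**: powers are clipped at 1e-9 so ratio biomarkers are always
  defined.
* `adhd_strain_scenario` plants study-like structure: distinct strain
  offsets in each of the five low bands (every pairwise strain contrast
  informative), depressed lDelta/Theta drift in SHR on every day, and
  dose-proportional Theta/Alpha slopes on the agent days; Total, Gamma,
  High and vHigh carry no strain signal. Effect sizes are strong by
  design, mirroring the large strain F-statistics and >80% per-band CV
  rates such experiments report.

What the generator does **not** emulate: biophysical EEG (no raw-signal
synthesis beyond the spectral module's own input path), electrode
geometry, animal random effects (curves are exchangeable within strain),
non-linear pharmacokinetics (trends are linear by construction), or
artifact taxonomy. Passing tests therefore demonstrate correctness of
the *pipeline* under its own model class, not rodent realism.

## Median filter

Centred moving median with the window truncated (shrunk) at the series
boundaries, so length is preserved and boundary windows of even size use
the arithmetic median. The default window of 241 samples (~1 min at
250 ms) is a prominent knob: the appropriate width scales with the
sampling step, and analyses on coarser grids should scale it down
(tests and the acceptance script use ~1 min equivalents). The filter is
idempotent on constants and never leaves the input's range.

## Functional boxplot

Curves within a (strain × day × band) group — channels and animals
pooled, 50 curves per group in the full design, 216 groups — are ranked
by modified band depth with J = 2: the average over all unordered curve
pairs of the fraction of time the curve lies inside the pair's pointwise
envelope, pairs containing the curve counting as fully inside. Depth is
computed exactly from per-time-point ranks in O(nT log n); ties are
handled so tied curves contain each other (verified against the direct
O(n²T) oracle). Plain band depth (J = 2, all-or-nothing containment) is
available as an option. The central region is the envelope of the
deepest ⌈n/2⌉ curves (depth ties broken by input order, for
determinism); fences inflate it pointwise by 1.5× its height; a curve is
an outlier iff it exits the fences at one or more time points. Flags are
a pure, permutation-equivariant function of the inputs. Re-computing
fences after removing a flagged curve can in principle flag new curves;
no iterative re-fencing is performed.

## Features

The regression window is half-open [2, 51) minutes after injection —
the first two minutes are discarded as handling artefacts, and the
half-open end avoids double-counting the boundary sample (11 760 samples
at 250 ms). Slopes are in power units per *minute*; the intercept is the
fitted level at the injection instant. mPower uses the same window as
the regression (whether the historical grand mean was windowed
identically is unknowable from the published record; sharing the window
makes the three parameters directly comparable). By default, curves
flagged as outliers are excluded from the feature table; a flag retains
them. Feature matrices order columns day-major, then band in canonical
order, then parameter (slope, intercept, mPower) — 8 days × 9 bands ×
{slope, intercept} gives the canonical 144-dimensional sample vectors,
one per (strain, animal, channel), 150 rows in the full design.

## ANOVA and t-tests

The observation unit is one (animal × channel) sample — 50 per
strain-day cell. Channels within an animal are pseudo-replicates; a
mixed-effects model with animal random effects would be the stricter
analysis and is deliberately out of scope, so the F-statistics should be
read as descriptive rankings rather than strict inferences. Balanced
designs use the closed-form textbook sums-of-squares decomposition
(Type I, identical to Type II under balance; verified against
statsmodels); unbalanced designs (after outlier removal) delegate to
statsmodels' Type II ANOVA. Degrees of freedom in the default design:
condition 7, strain 2, interaction 14.

t-tests are pooled-variance Student by default (Welch optional),
reported one-tailed in the direction of the observed mean difference
together with that direction's sign. A test whose direction is chosen
post hoc rejects at 2α overall; the calibrated quantity — verified at
α = 0.05 over 1000 null simulations — is the per-direction error rate
(falsely declaring a *positive* effect), which is what the
direction-coded significance marks represent. Zero-variance degenerate
input follows the convention: equal means → p = 1, unequal → p = 0.
No multiple-testing correction is applied by default (per-test marks at
0.05/0.01); a Benjamini–Hochberg helper is provided.

## Fisher discriminant analysis

Per-class covariances use the unbiased 1/(n_c − 1) normalisation and
S_W = S₁ + S₂ (a sum, not a pooled-weighted estimate). The weights are
the closed form w = S_W⁻¹(μ₁ − μ₂); ridge regularisation is exactly
zero unless S_W is numerically singular (solve failure or relative
residual > 1e-6), in which case it escalates to 1e-8·tr(S_W)/dim and the
magnitude used is recorded in the model. The threshold
z₀ = (s₂⟨w,μ₁⟩ + s₁⟨w,μ₂⟩)/(s₁+s₂) with s_c = √(⟨w, S_c w⟩) sits between
the projected means, closer to the tighter class; the boundary itself is
assigned to class 1 (⟨w,f⟩ ≥ z₀). Decisions are invariant under
orthonormal feature maps and per-feature rescaling (asserted in tests);
general affine invariance holds for the closed form but is only asserted
where it is exact.

Cross-validation partitions samples uniformly at random (seeded,
unstratified) into k near-equal folds; a partition in which a training
fold loses a class is re-drawn (at most 100 attempts). Rates are
reported in percent with the SEM over folds; the classification grid
averages over 10 independent partitions by default and evaluates
2-dimensional (band × day), 16-dimensional (band × all days),
18-dimensional (day × all bands) and 144-dimensional (all × all)
feature subsets for each pairwise strain objective. Grids are
bit-reproducible for a fixed seed.

## Biomarker search

Candidate bands must (a) show strain significance at α = 0.01 in the
two-way ANOVA for at least two of the three parameters and (b) reach a
median pairwise CV rate ≥ 80% (configurable) in their all-days grid row;
the aggregate Total band is excluded. Weight reports fit the FDA on
bootstrap resamples (class 1 = target group) and normalise each weight
by its feature's standard deviation before scaling to unit L1 norm —
bands whose raw scales differ by orders of magnitude become comparable
while decisions are untouched. Note that the bootstrap SEM describes
resampling variability around the *dataset's* discriminant direction,
not the across-experiment null (the tests check the null across
independent datasets instead).

Consolidation takes the top-k mPower weights by magnitude (positive →
numerator, negative → denominator; ties broken by canonical band order)
and the top-k slope weights as a signed linear term, emitting one
proposal per λ ∈ {0.1, 0.01}; proposals are ranked by the one-tailed t
statistic on a held-out half of the samples so the reported separation
is not the one the heuristic optimised. The nine published composite
forms ship as presets; strain biomarkers are evaluated on the vehicle
day (D1) by default, agent biomarkers on dose days against the vehicle
day within a strain.

## Problem sizes and runtime choices

Tests and the acceptance script run the full 3 × 10 × 5 × 8-day, 9-band
design but on a 5–10 s time grid with a ~1-minute median window; every
design count (150 samples, 144 dimensions, 216 groups, 50 curves/group)
is invariant to the grid, and the 11 760-sample window arithmetic is
checked at the true 250 ms step on a single record. Calibration
experiments use 1000 null replicates (exact binomial 99% acceptance
bands), 2000 samples for the Gaussian Bayes-rate check and 50 seeds for
the permutation null.

## Known limitations

* The spectral estimator (rectangular-window periodogram) is the
  simplest reproducible choice; tapered or multitaper estimators would
  reduce leakage between neighbouring bands.
* Channels are treated as independent samples throughout, inflating
  nominal significance; see the ANOVA caveat above.
* The search heuristic explores only ratio-of-products plus signed-sum
  forms with the two published λ values; no exhaustive combinatorial or
  continuous-λ optimisation is attempted.
* EDF input requires the optional `mne` dependency and is exercised only
  through its CSV-matrix fallback in the test suite.
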