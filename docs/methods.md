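# Methods

This note documents the models and procedures implemented in `strainpheno`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Signal model and preprocessing

A recording is one cardiac cycle of LV longitudinal strain, sampled at the
acquisition frame rate, annotated with three ECG landmarks: the R-peak
(cycle start, strain ≈ 0), aortic valve closure (AVC, end-systole, strain
near its extremum) and the P-wave (atrial activation, end of diastasis).
Strain is stored signed (physiologically negative); all features and
reports use magnitudes, matching the convention of reporting peak
longitudinal strain as a positive percentage.

Quality control excludes recordings below a minimum frame rate (default
45 Hz), with non-monotone time axes, missing or mis-ordered landmarks, or
a sampling interval inconsistent with the declared frame rate; each
exclusion carries a machine-readable reason code.

Alignment is segment-wise: each trace is split at (R, AVC, P) and each of
the three segments is linearly resampled onto the maximum native sample
count of that segment over the cohort, so landmarks occupy identical
indices in every aligned curve.  Whole-curve resampling was rejected
because only per-segment resampling puts the landmarks at shared indices.
The aligned curve keeps a *subject-specific* time axis (the common index
grid maps back to each subject's own segment durations): slopes in %/s and
durations in seconds therefore keep their physical meaning, which a single
shared time axis would destroy by warping time.  Interpolation is linear
throughout — consistent with the piecewise-linear treatment of the curves
and free of spline overshoot.  Strain rate is the first difference of
strain over time on the native grid; its cumulative re-integration returns
the strain curve exactly, which the tests assert.

## Phase segmentation and the six features

Each aligned curve is approximated by an interpolating piecewise-linear
function through `n_knots` (default 5) interior knots chosen among the
sample positions to minimize the residual sum of squares.  Because the
approximation passes through the data at the knots, segment costs decouple
and an exact dynamic program (prefix-sum segment costs, deterministic
tie-breaking) finds the global optimum; the RSS is non-increasing in
`n_knots` by construction.  A continuous free-knot fit would couple the
segments and admit no exact DP; the interpolating variant is the
implemented definition.

Phases are derived from the fitted segments:

* **systole**: R-peak to the global peak of strain magnitude;
* **diastasis**: a fitted segment between the peak and the P-wave is a
  plateau candidate if its interior least-squares slope magnitude is below
  the plateau threshold (default 10 %/s) and its level lies below 0.75 of
  the peak (the diastasis sits in the lower part of the release;
  height/peak is roughly 0.25–0.65 physiologically, while smoothed peak
  corners and noise shelves sit near the peak).  The candidate closest to
  the P-wave is the core — the diastasis is the plateau immediately
  preceding atrial activation — merged with adjacent candidates.  Its
  onset and offset are refined to sub-sample precision by intersecting the
  plateau's interior-OLS line with the nearest long (≥ 45 ms) declining
  segment's line on each side; knots land within a sample of a (possibly
  rounded) corner, so interiors are trimmed before the fits.  When the DP
  spends no segment on a very short plateau, a ~50 ms sliding-window scan
  over the peak-to-P window is the fallback.  If no plateau exists the
  diastasis is empty and flagged degenerate;
* **early diastole**: peak to diastasis onset; **late diastole**: diastasis
  offset (capped at the P-wave) to the cycle end.

The six features are: least-squares slopes of strain magnitude versus time
over systole, early and late diastole (systolic slope positive, diastolic
slopes negative); diastasis duration (offset minus onset, using the
refined continuous times); diastasis height (mean magnitude over the
plateau; the onset-level variant is available in config); and peak strain
magnitude.  Degenerate-diastasis subjects get duration 0 and height equal
to the magnitude at the early/late junction, and are flagged; the feature
matrix contains no missing values.  Slopes are computed on the original
curve over the fitted phase boundaries, not on the interpolant.

## Mixture model and model selection

The six features are z-scored with training-cohort statistics (stored in
the model and reused verbatim when the frozen model is applied to an
external cohort).  A full-covariance Gaussian mixture is fitted by EM with
`n_init` (default 10) k-means++ initializations, keeping the best final
log-likelihood.  Full covariances were chosen because the phenogroups are
expected to differ in size and shape; a diagonal option exists in config.
Numerical safeguards: covariances receive a 1e-6 diagonal jitter; the EM
log-likelihood is asserted non-decreasing each iteration (with 1e-6
relative slack for the jittered M step); an initialization is abandoned if
a component's effective mass drops below d+1 points or a covariance
eigenvalue reaches the jitter floor — the degenerate-duration atom
(subjects with diastasis duration exactly 0) can otherwise capture a
collapsing component.

BIC = −2 log L + p ln n with p = (k−1) + kd + kd(d+1)/2.  The number of
phenogroups is the smallest k whose BIC decrease toward k+1 falls below
`elbow_fraction` (default 0.25) of the preceding decrease, ties toward
smaller k; `elbow_fraction = 0` returns the global BIC minimum, a
non-decreasing curve at k = 2 returns k = 1 with a warning.  The elbow is
made explicit and parameterized because flat BIC curves near the optimum
otherwise force a subjective choice between adjacent k.

Cluster labels are made canonical — reproducible across seeds and runs —
by ordering components by descending early-diastolic release rate
(ascending signed early-diastolic slope mean on the original scale):
cluster 1 is the fastest-relaxing, lowest-risk phenotype; the last cluster
the stiffest.

## Interpretation

Shapley values explain f_c(x) = posterior probability of cluster c.  The
estimator is permutation sampling with background imputation: for each
sampled feature ordering, a background subject's features are switched one
at a time to the explained subject's values, and the change in f_c is
credited to the switched feature, averaged over orderings and the whole
background set.  Efficiency (contributions sum to f_c(x) minus the
background mean of f_c) holds exactly for every ordering by telescoping;
with all d! orderings the estimator equals the exact Shapley value of the
game v(S) = E_b[f_c(x_S, b_−S)], which the tests verify against subset
enumeration on three features.  Forest importance is Gini
mean-decrease-impurity from a random forest trained to predict the hard
labels, normalized to sum to one, with the out-of-bag agreement rate as a
sanity check.  The radar profile divides each cluster's feature-mean
magnitude by the per-feature maximum across clusters.

## Outcome analysis

Incidence rates use the first event per subject: person-years accumulate
to the event or to censoring; rates are per 1,000 person-years.
Kaplan–Meier cumulative incidence is 1 − S(t) with Greenwood variance
(no competing-risk correction; a Fine–Gray option is out of scope).  The
Cox model maximizes the Breslow partial likelihood (solver tolerance
1e-12 so the score vanishes at the optimum to < 1e-6); cluster membership
is deviation coded, so the log hazard ratios sum to zero and each contrast
is against the cohort-average hazard — the omitted level is recovered as
−Σβ with a delta-method standard error.  Continuous covariates are scaled
per SD ("standardized" hazard ratios); pairwise cluster comparisons (Z
tests for means, χ² for proportions) are unadjusted for multiplicity by
default, with a Bonferroni switch.

Cohort-table utilities implement the outcome-derived echo rules: LV
hypertrophy as LV mass index > 50 g/m^2.7 (men) / 47 (women) — both
thresholds configurable — and LV diastolic dysfunction as E/e′ ≥ 9.5, or
borderline E/e′ in [8.5, 9.5) with any of low peak LA strain (< 23%), LA
enlargement (LAVI ≥ 45 ml/m²), tricuspid regurgitation velocity
> 2.5 m/s, or prolonged reverse atrial flow (mitral A-flow duration ≤ PV
reversal duration − 10 ms).  Missing inputs propagate as unknown under
Kleene logic, never as "no".

## The synthetic cohort generator

The generator is the package's validation instrument: it emulates a
community echocardiography cohort with four latent phenogroups and known
per-subject truth.  Each group has a template skeleton — zero strain at R,
linear systolic rise to peak at AVC, early-diastolic release to the
diastasis level, a plateau, then a late-diastolic decline — whose corners
are rounded by a 30 ms moving average (real curves are smooth; the window
is a config knob).  Subjects jitter the template parameters
multiplicatively (4% relative SD, truncated at ±2.5 SD and re-drawn so the
phases always fit the cycle), draw a heart rate from the group's range and
a frame rate from 45–80 Hz, and add white measurement noise (0.3% strain).
Landmarks are recorded exactly from the skeleton.

Default group templates span a gradient from a young phenotype (peak
≈ 19.8%, fast early release ≈ 70 %/s, long diastasis ≈ 0.25 s) to a stiff
one (peak ≈ 17.7%, slow release ≈ 34 %/s, short diastasis ≈ 0.07 s), with
covariate distributions (age, blood pressure, BMI, cholesterol, risk-factor
prevalences, diastolic echo indices) following the same gradient.  Two
design constraints keep the within-group feature distributions unimodal so
that the four-group contract the generator promises actually holds in
feature space: the late-diastolic slope of each template is capped so the
decline does not reach the zero-strain baseline for only a subset of a
group (a partial floor would split that group's late slope into two
regimes), and the late-diastolic window is never shorter than 120 ms
(atrial activation precedes the next R by roughly a PR interval; this also
keeps the late-slope estimate from degenerating to a handful of frames).
Recorded per-subject truth applies the feature functionals to the
continuous noiseless skeleton — in particular the late-slope truth is the
least-squares slope over the late phase up to the last recorded frame.

Events are exponential: the cardiovascular hazard is baseline
(0.011/person-year) times exp of the group's log hazard ratio (defaults
−1.2, −0.4, 0.4, 0.8); cardiac events are a 0.7 sub-hazard of the CV
hazard, so a cardiac event always implies a CV event; censoring is uniform
on 3–12 years.  No quantitative description of within-cluster curve
variance exists for the motivating cohorts; the jitter, noise level and
hazard defaults are plausibility choices, and cohort-level rates they
produce (≈ 11/1,000 py) are properties of those choices, not claims about
any real population.

What the generator does **not** emulate: speckle-tracking measurement
artifacts (drift, segment dropout, observer-dependent region-of-interest
choices), multi-beat variability, arrhythmia, competing risks, covariate
effects on the hazard (risk runs only through group membership), or
correlation between curve shape and covariates beyond shared group
membership.  Passing tests therefore demonstrate the pipeline's
correctness and its recovery of known structure under realistic sampling —
not that four phenogroups exist in any particular real cohort.

## Validation problem sizes and numerical choices

The test suite validates cluster-number selection and recovery on
n = 1000 cohorts (adjusted Rand index ≥ 0.9 across 10 seeds; BIC elbow at
k = 4), Cox coverage on 20 simulations of n = 2000, and the full
curve-to-hazard pipeline on 10 seeded n = 500 cohorts; these sizes give
stable statistics while keeping the default suite fast.  The noiseless
feature-recovery bound (all six features within 2% of truth) is checked at
100–120 Hz sampling with smoothing and noise off, where discretization is
the only error source; at 45 Hz the peak-strain sampling cut alone
(≈ s_up·s_down/(s_up+s_down) · Δt) exceeds 2%.  Determinism is enforced
end-to-end: every random operation takes an explicit seed, floats are
written with shortest round-trip repr, and a rerun with the same config
yields byte-identical feature matrices and model JSON.

Known limitations: the phase segmentation assumes a single strain peak
near AVC and one plateau between peak and P — biphasic or severely
dyssynchronous deformation patterns would need a richer phase model; the
elbow rule, though explicit, inherits the flat-BIC ambiguity between
adjacent k on weakly separated data; and the Shapley estimator's cost
grows linearly in background size, permutations and subjects explained,
so the pipeline explains a subsample by default.
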