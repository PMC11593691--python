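# Methods

## Scope

`tanspec` implements the chemometrics workflow used to grade powdered
*Salvia miltiorrhiza* (danshen) by hyperspectral imaging: black/white
reflectance calibration, row-wise spectral pretreatments, latent-variable
models for origin classification and tanshinone content prediction,
effective-wavelength selection, and RPD-based model grading.  Because no
public HSI dataset of this kind exists, the package ships a seeded synthetic
generator that reproduces the statistical structure the workflow assumes;
every claim the test suite makes is a claim about that structure, not about
field data (see "What the generator does and does not emulate").

## Wavelength axis

The default instrument is a dual-sensor push-broom imager: 108 VNIR channels
from 410 nm at a 5.4 nm pitch (last channel 987.8 nm) concatenated with 288
SWIR channels spanning 950-2500 nm.  Manufacturer-style range/step/count
triples are often mutually inconsistent, so the SWIR grid is constructed
from its channel *count* (the authoritative figure) with the step derived
from the range, (2500 - 950)/287 ~= 5.401 nm.  Segment tags travel with the
axis because derivatives must never difference across the sensor seam.

## Synthetic generator

Concentrations.  Each of five origins (SD, HB, SX, SC, AH) draws tanshinone
I, tanshinone IIA and cryptotanshinone contents from independent normal
distributions truncated at zero (negative contents are unphysical; several
origin SDs are large enough that truncation matters, e.g. HB cryptotanshinone
0.451 +/- 0.379 mg/g).  The total is always the exact component sum, never an
independent draw.

Spectra.  Absorbance is Beer-Lambert linear:

    A(lambda) = baseline(lambda, origin) + sum_k c_k * e_k(lambda)
    r = exp(-A),   x = a * r + b + eps

with one Gaussian absorption band per analyte (tan I 2220 nm, tan IIA
1740 nm, CTS 1300 nm; width 40-45 nm; amplitude 0.1 AU per mg/g, putting
peak analyte absorbances at realistic 0.01-0.4), shared water/C-H bands at
910/960/1120 nm, and a steep visible-region pigment edge that makes
reflectance rise sharply over 400-900 nm.  The observation model applies
sample-wise affine scatter, a ~ N(1, 0.05), b ~ N(0, 0.005), plus iid
channel noise eps ~ N(0, 0.003) — exactly the distortion family MSC and SNV
are designed to remove, which makes pretreatment benefits testable against
known truth (the per-sample a, b are recorded in the dataset).

Origin colour bands.  Each origin additionally carries one fixed Gaussian
absorption band in the visible region (450-680 nm, amplitudes 0.12-0.35).
Powders from different provenances differ visibly in colour, and without an
origin-specific spectral component beyond the three analyte concentrations
the SX/SC/HB classes would be statistically inseparable (their concentration
means sit within roughly one SD of each other).  The colour band is part of
the baseline term, so the Beer-Lambert concentration linearity is untouched.

What the generator does *not* emulate: particle-size-dependent scattering
physics, imaging geometry, illumination nonuniformity beyond the affine
model, instrument drift, wavelength-correlated noise, or chemical-matrix
covariation between analytes and other constituents.  Synthetic spectra are
consequently cleaner than field data — full-wavelength PLSR reaches RPD
values well above the 3-4 typical of real powder calibrations — so passing
tests demonstrate correctness of the algorithms and the expected *ordering*
of methods, not field-level error bars.

## Pretreatments

SNV normalizes each row to zero mean and unit SD (ddof=1).  MSC regresses
each row on a reference spectrum and removes the fitted slope/offset; the
reference is the calibration-set column mean, and prediction rows are
corrected against that same reference to avoid information leakage.  SG
smoothing and the D1/D2 derivatives are Savitzky-Golay local polynomial
fits (default window 11, polyorder 2 — standard chemometrics practice; the
derivative scale is per channel index).  Edge channels are evaluated from
the edge-window polynomial so the channel count is preserved.  On the
two-sensor axis each segment is filtered independently.

## PLS models

PLSR is NIPALS with X and Y mean-centering and no variance scaling.  For a
single response the inner loop is closed-form; deflation makes every nested
model with fewer components available from one fit, which the
cross-validated component selection exploits.  Invariants enforced by tests:
score orthogonality, equivalence to ordinary least squares at full rank,
non-increasing training RMSE in the component count, and prediction of the
training mean response at the training mean spectrum.

PLS-DA regresses a one-hot class indicator matrix by PLS2 and predicts the
argmax of the predicted indicators (ties to the earlier class).  The
component count is chosen from 4-15 by stratified 5-fold CV accuracy, ties
to the smaller count.

BPNN, SVM and RF are contracts over scikit-learn: a single-hidden-layer
perceptron (10 logistic units, linear output, lbfgs up to 500 iterations,
inputs and response standardized internally), an RBF-kernel SVC (C=1,
gamma=1/n_channels, standardized features), and a 500-tree random forest.
All are seeded and deterministic.

## Wavelength selection

SPA grows a deterministic chain from every starting channel by repeatedly
adding the channel whose column has the largest norm after projection onto
the orthogonal complement of the selected span; each chain prefix
(default lengths 5-60) is scored by MLR RMSE on a held-out quarter of the
calibration set, and the global minimum wins (ties: shorter chain, then
smaller start).  Prefix models are evaluated via a single QR factorization
per chain.

VISSA holds a weight in [0,1] per channel (start 0.5) and iterates weighted
binary matrix sampling: 1000 random channel subsets drawn Bernoulli(w_j)
per channel (rows with fewer than two channels are redrawn), each scored by
5-fold CV RMSE of a PLS submodel capped at 10 components, the best 5% kept,
and the weights replaced by the survivors' inclusion frequencies.  Iteration
stops when every weight is 0 or 1 (absorbing states) or after 50 iterations;
channels with final weight >= 0.5 are selected.  The submodel scorer is an
independent SIMPLS implementation (identical to NIPALS for one response,
dominant-eigenvector generalization for indicator matrices), JIT-compiled
with numba when available, with a pure-numpy reference path that tests
verify bit-agrees.

The VISSA validation benchmark uses 60 samples — a deliberately small,
realistic NIR calibration size — with 5 informative channels
(coefficients 3, -2, 2.5, 1.5, -3), 95 pure-noise channels, and response
noise SD 0.3.  Small calibration sets sharpen the penalty for dragging
noise channels into a submodel; a known artifact of frequency reweighting
is that a few noise channels can random-walk to the absorbing weight 1
before the selection pressure removes them, which is why the benchmark
asserts a *mean* final noise weight rather than zero retention.

## Evaluation

Splits are stratified by origin with seeded shuffling: 7.5:2.5 for
classification (63/21 per origin at n=84) and 7:3 for regression (59/25).
R-squared is the squared Pearson correlation (coefficient of determination
available via `r2_mode="determination"`); RMSE is the plain root mean
squared error of the evaluated set; RPD is the evaluated set's reference SD
(ddof=1) divided by that RMSE, reported as +inf for a perfect fit.  Grades
combine an R-squared band with an RPD band — very good (>0.90, >3.0), good
(0.80-0.90, 2.5-3.0), usable (0.60-0.80, 2.0-2.5) — and a disagreement
resolves to the lower band.  Band edges are half-open with strict
inequalities at 0.90/3.0, so (0.90, 3.5) grades "good", and the rule is
monotone in both inputs (property-tested).

For mean-centered predictions RPD ~= 1/sqrt(1 - R^2); published tables
occasionally violate this identity (notably for random-forest rows), which
usually traces to a different SD convention.  The package computes RPD one
way only and documents the identity rather than asserting it on external
numbers.

## Pipeline and reproducibility

All orchestration derives per-stage seeds from one root seed by hashing
(stage name, root seed), each below 2^31, so the full run is
bit-reproducible and stages are insensitive to each other's consumption of
random numbers.  One split is shared within each grid so model comparisons
are paired.  Every grid cell is logged with (stage, seed, config-hash).
The "total" target is modeled directly (as published tables do); the sum of
the three component models' predictions is reported as an additional
diagnostic, not a replacement.

Problem sizes: the default study is 420 samples x 396 channels.  The
acceptance script runs the full grids at that size; the test suite
exercises the same code paths on a 60-channel mini axis with 80 samples,
plus the full-size end-to-end regime checks, keeping the default `pytest`
run around one minute.

## Known limitations

* ENVI I/O covers the common BSQ/BIL float cubes only (no tiled or
  compressed variants).
* Model persistence (JSON) covers the PLS family; the sklearn-backed
  learners hold unexported estimator state.
* SPA's evaluator is MLR on a single held-out split, the classical choice;
  a CV evaluator would be slower and is not implemented.
* The generator's class signal is concentrated in the visible region by
  construction; selection on classification tasks therefore tends to pick
  VNIR channels, which is a property of the synthetic design, not of real
  danshen spectra.
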