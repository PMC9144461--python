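# Methods

`emgdecode` re-implements, as a tested and reusable pipeline, a 15-class
finger-movement decoder for 8-channel forearm surface EMG: multivariate
outlier elimination, windowed time-domain feature extraction, Gaussian
discriminant classification with feature selection and normalization,
nested cross-validated evaluation with ANOVA/Duncan validation, and the
translation of classifier decisions into OpenSim-loadable motion files.
This note records the model assumptions, the parameters that matter, the
numerical choices, and what the synthetic database does and does not show.

## The data model

The pipeline assumes a database tree of one directory per subject and one
headerless CSV per movement (8 float columns = sEMG channels).  The default
acquisition protocol is 8 subjects x 15 movement classes x 12 repetitions,
each repetition 5 s at 4 kHz, giving 20,000 rows per repetition, 240,000
rows per movement file, and a 28,800,000-row global matrix once a class
label is appended as column 9.  The movement classes are flexions of the
individual fingers (T, I, M, R, L), ten two- and three-finger combinations,
and the closed hand (HC); labels 1..15 follow the fixed abbreviation order
in `emgdecode.dataio.MOVEMENTS`.

## Outlier elimination

An irregular electrode reading invalidates the whole 8-channel sample, so
rows are removed whole.  The mean and covariance of the 8 channels are
estimated once over the *entire* assembled matrix, each row's squared
Mahalanobis distance is compared against the central chi-square quantile
with 8 degrees of freedom (the label column is excluded), and rows above
the critical value are dropped.  The probability level defaults to
p = 0.999 and is configurable; under multivariate normality the expected
removal is 1 - p, but sEMG amplitudes are strongly non-Gaussian (burst
envelopes), so the realized removal on the synthetic database is a few
percent.

Numerical choices and caveats:

- the covariance receives a ridge `1e-9 * trace/8` on its diagonal before
  factorization; a covariance still singular after that is reported as a
  labelled error;
- the stage runs *before* any train/test split, exactly as in the
  replicated procedure.  The induced leakage (test rows influence the
  removal statistics) is documented, not fixed;
- mean/covariance outlier detection is subject to *masking*: rows that are
  extreme enough, or frequent enough, inflate the estimated covariance and
  hide both themselves and milder outliers.  With the synthetic artifact
  injector this is plainly visible — raising the artifact rate from 0 to
  5% *lowers* the number of removed rows.  The tests assert the stage's
  self-consistency rather than a monotone removal count.

## Windowing and features

Kept rows are chopped into non-overlapping 250-row windows (62.5 ms at
4 kHz).  Windows never span a class-label change; the final window of each
contiguous movement block holds the remainder (1..250 rows).  For each
window, 12 time-domain features per channel are concatenated channel-major
into a 96-vector, with the class label as column 97:

MAV, MSV (mean of squares), SSI, RMS, VAR, TM3/TM4/TM5 (absolute time
moments), WL, ZC, MYOP, SSC — definitions in `emgdecode.preprocess`.

Two readings deserve a note:

- **"square mean" vs "mean square value"**: the feature list names both;
  they are implemented as RMS and the mean of squares respectively, the
  only reading in which the twelve features are distinct;
- **VAR** uses the zero-mean convention `sum x^2 / (N-1)` standard for
  band-passed EMG, not a mean-subtracted variance;
- degenerate windows of a single row define WL = ZC = SSC = VAR = 0.

Thresholds: ZC and SSC default to 0 (pure sign tests); MYOP's amplitude
threshold defaults to 0.016, about twice the synthetic generator's baseline
RMS, so rest segments score near zero.  All three are configurable and none
has a canonical published value.

Normalization (z-scoring to zero mean, unit sd) is fitted on training rows
only and applied with those statistics everywhere; constant features map to
exactly 0 (sd substituted by 1).

## Classifiers

Naive Bayes, LDA and QDA are implemented from scratch as explicit per-class
discriminant functions

    g_k(x) = ln pi_k - 1/2 ln|Sigma_k| - 1/2 (x - mu_k)' Sigma_k^-1 (x - mu_k)

with per-class diagonal variances (NB), a single pooled covariance (LDA),
or per-class full covariances (QDA).  Priors are class frequencies.
Scores are evaluated in log space through Cholesky factorization; ties in
the argmax resolve to the lowest class label.  Every covariance receives a
ridge `lambda * trace/d` on the diagonal, `lambda = 1e-6` by default: with
96 features and as few as a dozen windows per class in an inner training
fold, the sample covariances are rank-deficient and the ridge is what keeps
the quadratic discriminant defined.  This regularization is also why the
unnormalized-QDA treatment behaves poorly: raw features span ~10 orders of
magnitude (SSI vs ZC), so a trace-proportional ridge swamps the small-scale
features.  Models serialize to JSON (priors/means/covariances), so the
fifteen sum-of-products discriminants can be exported to embedded targets.

## Feature selection and the sparse projection

Sequential forward selection is the standard greedy wrapper: evaluate every
remaining feature joined to the current subset, accept the argmax only on
strict improvement (ties to the lowest index), stop at stagnation.  The
default evaluation is training-set recognition of the chosen classifier.
In the cross-validated experiments, SFS runs **once per dataset and
classifier** and the selected subset is then cross-validated — this mirrors
the replicated procedure ("the groups of features were saved ... the data
were taken again and separated"), and the implied optimism is documented
rather than patched.  An `sfs_scope="outer_fold"` mode reruns the selection
inside every outer training block for leakage-free estimates; the leakage
property test uses it.

The sparse-space conversion is implemented as a supervised projection: the
generalized eigenvectors of the between-class vs within-class scatter
(Fisher criterion), with an element-wise soft-threshold on loadings as the
sparsity mechanism and deterministic sign/ordering conventions.  The
published description specifies only the objective ("increase the distances
between the evaluated classes, reduce the distances within a class") and
the empirical outcome (no gain over the untransformed baseline); the
algorithm choice is isolated behind `SparseSpaceModel` so it can be
swapped.  With all components retained and zero penalty the map is
invertible and QDA is exactly invariant, which is what produces the
observed saturation-at-baseline behaviour.

## Evaluation protocol

The nested 10x10 cross-validation: a stratified outer 10-fold split
separates TST from TRN-VAL; each TRN-VAL block is split again into 10
stratified TRN/VAL folds.  Each of the 100 fitted models is scored on its
TRN, VAL, and its outer fold's TST; per-outer-fold TST is the average over
the 10 inner models.  Stratification is a deliberate choice (the source
procedure does not specify it): at synthetic scale an unstratified split
can lose a class from a training fold entirely.

The experiment grid crosses {NB, LDA, QDA} x four treatments (A =
normalization + SFS, B = normalization, C = SFS, D = none) x {each subject,
pooled}.  The per-subject QDA test percentages per treatment feed a one-way
fixed-effects ANOVA and Duncan's multiple range test.  Duncan's significant
ranges are computed exactly from the studentized-range distribution at the
protection level `1 - (1-alpha)^(p-1)` (scipy's `studentized_range`),
rather than from interpolated printed tables; spot checks against the
classical table values (e.g. r_.05(2,20) = 2.95) are in the tests.  The
standard containment rule applies: no pair inside a non-significant span is
declared significant.  Only the equal-group-size form is implemented.

## Motion synthesis

Each 62.5-ms window decision selects a 21-coordinate advancement vector
(degrees per video frame) for the decided movement class; accumulating
vectors from a zero posture builds the motion matrix, and 80 decisions span
one full 5-s repetition, so an ideal movement is its own vector accumulated
80 times (81 rows including the zero posture; a flag drops the zero row).
Hand close is the special case: the first 18 HC frames flex the fingers
only (HC1), later HC frames add the thumb (HC2); the 18-frame switch is
implemented verbatim from the source pseudocode, and the counter persists
across the whole decision stream (a single counter variable, not reset per
HC run).  Angles are emitted in degrees — the table magnitudes force this
reading (1.4516 deg/frame x 80 frames = 116.128 deg, a full finger
flexion).  Files use the OpenSim motion text dialect (`version=1`, `nRows`,
`nColumns`, `inDegrees=yes`, `endheader`) and round-trip exactly through
the shipped reader.  Streams shorter than 80 decisions (outlier-trimmed
repetitions) are supported.

## The synthetic database

The generator emulates the protocol dimensions exactly and the signal
statistics plausibly:

- each channel is zero-mean Gaussian noise band-limited to 20-450 Hz
  (4th-order Butterworth, zero-phase), whose RMS follows a trapezoidal
  activation envelope — rest 0.5 s, ramp 1 s, hold 2.5 s, release 1 s at
  the 5-s default, scaled proportionally otherwise — on top of a constant
  baseline (RMS 0.008, arbitrary units);
- class identity enters through a class x channel activation map built
  from which fingers each movement flexes, with neighbouring fingers
  sharing channels (thumb ch 1-2, index 2-3, middle 4-5, ring 5-6, little
  7-8, all-summed for HC).  Shared channels make neighbouring movements
  genuinely confusable, which is what gives the classifier comparison
  something to measure;
- subjects differ by log-normal gain jitter (sigma 0.15) on the map;
  repetitions differ by log-normal amplitude jitter (sigma 0.25) and
  +/-10% envelope-timing jitter.  These spreads were fixed once, as
  plausible trial-to-trial and person-to-person variability, before any
  downstream result was inspected;
- the artifact injector multiplies one random channel of a Bernoulli
  subset of rows, as a fixture for the outlier stage.

What the synthetic data does *not* model: motor-unit physiology, electrode
crosstalk geometry, line interference (the source data is notch-filtered),
12-bit ADC quantization (floats throughout), and any amplitude calibration
— the absolute scale is arbitrary and never used downstream.  All twelve
features are amplitude/complexity statistics that respond to RMS
modulation, which is why the filtered-noise-times-envelope model is
sufficient for exercising the pipeline.  Passing grid tests therefore show
that the *pipeline* orders treatments and scopes as expected when the data
have the assumed structure; they do not certify recognition percentages on
real recordings, and the published headline rates (96.16% per-subject,
78.36% pooled) are properties of the real database and original fitting
routine, not reproduction targets here.

## Problem sizes used in tests and the acceptance script

The statistical validation stage runs on the bundled published 8x4
treatment table and is exact.  The experiment grid runs on a reduced
synthetic database — 2-s repetitions, 4 repetitions per movement, 8
subjects, 15 classes (3.84 M raw rows, ~14 k windows) — chosen so a full
grid (12 classifier x treatment cells x 9 datasets x 100 fitted models
each) completes in minutes on one CPU while keeping every class above the
stratification minimum.  Unit tests use micro protocols (2 subjects, 3-4
classes, 0.5-1-s repetitions).  The full-protocol dimensions are verified
structurally (counts, shapes, file sizes) rather than by running the grid
at full scale.

## Known limitations

- Exact-number parity with the published recognition tables is out of
  reach by design (real data, unknown fitter internals); only in-table
  statistics (ANOVA/Duncan on the printed values) are reproduced
  numerically.
- Duncan's test handles equal group sizes only (harmonic-mean extensions
  are out of scope).
- The outlier stage and dataset-scope SFS leak information across the CV
  split because the replicated procedure does; leakage-free variants exist
  behind flags but are not the default.
- The generator's defaults are plausibility choices, not fits to the real
  database, whose amplitude distribution and SNR are uncharacterized.
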