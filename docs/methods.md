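# Methods

## The paradigm and what the package simulates

The task is a 3 (benefactor intention: strong / weak / no) × 3 (benefit
value: high / low / zero) × 2 (emotion: gratitude / joy) within-subject
design. A trial shows a scenario screen for 3 s ("your friend wants to help
you X%", "who gives you ¥Y"), then two rating screens in which the subject
rates gratitude and joy on a 3-point scale; three 0.5 s fixations and rating
durations drawn from {8/4, 7/5, 6/6, 5/7, 4/8} s make every trial exactly
16.5 s. A run holds 20 trials — two per factorial cell plus two nulls — in
pseudo-random order such that consecutive condition trials never share an
intention or a value level (nulls are transparent to this constraint). The
rating order alternates across runs in one of two counterbalanced schemes
(A-B-B-A-A-B or B-A-A-B-B-A), assigned to alternating subjects. Default
acquisition geometry: 145 volumes per run at TR 2.3 s; trials tile from t=0,
so the last trial ends at 330 s ≤ 333.5 s of scanning.

Scenario percent and amount are integer-uniform over the level's range
(95–100 / 7–12 / 0 percent; 800–1200 / 80–120 / 0 currency units). The
five rating-duration splits are drawn uniformly per trial by default; a
balanced-blocks option assigns each split exactly four times per run. Null
trials are placed uniformly at random. Schedule search is randomized
backtracking with a restart budget; an infeasible cell multiset raises.

## Behavioral generator

Ratings come from a latent Gaussian model discretized to {1, 2, 3} at
cut-points (1.5, 2.5): latent = grand mean (1.95) + intention main effect
(+0.45 / −0.05 / −0.40) + value main effect (+0.55 / 0 / −0.55) ± half the
gratitude-minus-joy cell difference + subject intercept (SD 0.20) + residual
noise (SD 0.50). The gratitude-minus-joy difference matrix is the model's
emotion-effect structure; its default is nonzero only for strong intention
with low (0.24) or zero (0.37) value, so gratitude exceeds joy exactly where
the appraisal account predicts: when someone strongly wanted to help but the
benefit itself was small. The emotion main effect and the emotion-by-factor
interaction weights are the sum-to-zero decomposition of this matrix,
exposed as properties. Each rating is independently missing with probability
0.02 (nonresponse). The latent cell means are available in closed form
(`RatingEffectParams.latent_cell_means`), which the tests use as an analytic
oracle: as the noise SDs shrink, every empirical rating equals the
discretized closed-form mean.

## BOLD generator

Per voxel, signal = Model-1-style condition regressors × ground-truth
amplitudes + Model-2-style onset/modulator columns × ground-truth slopes.
The modulator signal is injected through the *orthogonalized* modulator
columns by default — exactly the columns Model 2 fits — so noiseless
simulations are recovered to numerical precision; a raw-modulator option
exists for studying the orthogonalization transform itself. Noise is AR(1)
Gaussian per voxel (default φ = 0.3, innovation SD 1.0), optionally smoothed
spatially at a Gaussian FWHM in mm and rescaled to preserve the marginal SD;
smoothing applies to the noise field only, which yields the spatial
correlation of preprocessed data without perturbing the planted signal.
Voxels outside the brain mask (an ellipsoid inscribed in the grid by
default) are zero. Six slow-drift random-walk series per run stand in for
realignment parameters so the design matrices keep their full nuisance
structure. The default test grid is 6×6×6 voxels at 3 mm isotropic
(configurable up to realistic sizes); ROI label maps mark disjoint voxel
sets whose modulation slopes differ between emotions.

What the generator does **not** emulate: hemodynamic nonlinearity,
physiological noise, motion artifacts in the images themselves, and
anatomical structure. Passing tests therefore demonstrate the statistical
machinery — estimability, calibration, recovery — not robustness to the
full messiness of real fMRI data.

## First-level GLMs

The canonical response is the double-gamma (peak ≈ 5 s, undershoot ≈ 15.5 s,
unit peak), convolved on a 16× oversampled grid and sampled at volume
onsets. GLM events are the rating screens with their variable durations:
Model 2 explicitly models "rating events", and labeling the same events by
cell and emotion keeps Model 1's 18-predictor structure coherent (the
scenario screen is an alternative convention, available by building events
differently). Trials with either rating missing are dropped from both
models, mirroring the behavioral exclusion.

Model 2's modulators are processed per emotion in fixed order — emotion
rating (the recorded 1–3 rating), intention linear (1/0/−1), intention
quadratic (the square, 1/0/1), value linear (1/0/−1) — by mean-centering
over events followed by serial orthogonalization (each modulator residualized
against all earlier ones; centering is the residualization against the onset
regressor), *before* convolution. Centering and orthogonalization span the
concatenated runs. A modulator with zero variance is dropped with a warning.

Runs are concatenated with per-run intercepts; no high-pass filtering by
default. The rating-order indicator is a run-constant ±1 column; because it
is run-constant it is linearly dependent on the run intercepts, so the full
design is rank-deficient by one. Fitting uses minimum-norm least squares
with a warning in that case; the deficiency lives entirely in the nuisance
subspace, so condition and modulator coefficients remain unique (asserted in
the tests). Fitting is OLS without prewhitening; degrees of freedom are
n_timepoints − rank(X).

## Group inference

The interaction contrasts spread each printed formula term evenly over the
collapsed factor's levels and negate the joy block: e.g. emotion-by-value
puts −1/3 on each gratitude high-value cell and +1/6 on each low- and
zero-value cell. One-sample and paired t maps use the classical formulas;
t is transformed to Z through the probability transform and capped at
|Z| = 10; zero-variance voxels are flagged (identical nonzero values cap,
identical zeros give t = 0).

Cluster-extent correction simulates smooth Gaussian null fields on the
analysis mask: white noise, Gaussian smoothing at the supplied or estimated
FWHM, restandardization to unit variance over the mask (skipped when FWHM is
0, where white noise is already standard — this also makes the white-noise
null exactly Bernoulli per voxel, which the tests exploit as an
order-statistic oracle). Each field is thresholded one-sided at the voxel p
and the maximum suprathreshold cluster size recorded; the critical size is
the smallest extent whose null probability is ≤ 0.05. Defaults: 26-
connectivity, 10,000 simulations in production and 1,000 in tests. Because
cluster sizes are integers, the achieved FWE rate sits at the largest
attainable value ≤ 0.05 (≈ 0.04 on the 6×6×6 test mask), not exactly at
the nominal level. Smoothness is estimated from per-voxel-standardized GLM
residuals by inverting the lag-1 spatial autocorrelation under the Gaussian
ACF model ρ(d) = exp(−d²/4s²) — the same model the null simulation uses,
keeping estimation and simulation self-consistent. Unmodeled structured
signal inflates this estimate (and hence the critical size), which errs
conservative. The significant tier uses voxel p < 0.001; clusters passing
only p < 0.005 are reported as trends.

## MVPA

Features are in-mask voxels of unsmoothed per-subject modulation-slope beta
maps, two samples (gratitude, joy) per subject. Each leave-one-participant-
out fold: min–max scale every feature to [0, 1] on the training samples
(test samples transformed with the same parameters, unclipped; zero-range
features map to 0); retain features whose gratitude-minus-joy paired t
across training subjects has two-tailed p < 0.05 (features constant in
training are dropped; pairs broken by permuted labelings drop out of the
test); train a linear SVM with C = 1; predict the held-out pair. A decision
value of exactly 0 predicts gratitude (deterministic tie-break). Accuracy is
correct/(2n); specificity and sensitivity are the gratitude- and joy-sample
accuracies, so with equal class counts accuracy is their mean.

The permutation test reruns the complete cross-validation (scaling and
selection included) under permuted labels. The default scheme permutes the
whole label vector; a within-subject pair-flip scheme (which preserves the
paired structure exactly) and a training-only relabeling variant are
provided, since the original procedure's scheme is ambiguous. The p-value is
the fraction of permutations strictly exceeding the observed accuracy; a
safeguarded (count+1)/(n+1) variant is available. Localization intersects
the fold-wise selected-feature masks, averages absolute SVM weights over
folds on that consensus set, and reports clusters of at least 5 voxels.

A caveat the test suite documents explicitly: LOPO fold predictions share
training data and are positively correlated, so the null distribution of
accuracy is wider than the binomial for 2n independent draws (measured SD
≈ 0.125 vs 0.065 at n = 30 with 200 null features) although unbiased at
0.5. Chance should therefore be assessed by the permutation test — whose p
is uniform under the null — not by binomial bands.

## Problem sizes

The test suite and the acceptance script run scaled-down but structurally
complete problems chosen as the package's own defaults: 6×6×6 or 8×8×8
grids at 3 mm, 12–30 subjects, 1,000-draw cluster nulls, 100-permutation
MVPA tests, 50–100 generator seeds for calibration checks. Production-scale
values (10,000 cluster simulations, 1,000 permutations) are the CLI
defaults.
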