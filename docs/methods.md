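# Methods

This note documents the models, the synthetic data the tests run on, the
numerical choices, and the known limitations of the package.

## Reflectance calibration and spectral extraction

Raw digital numbers are converted to relative reflectance elementwise,
R = (I_raw − I_dark)/(I_white − I_dark). Reference frames may be full cubes
or single scan lines broadcast along the transport axis (line-scan
geometry). Any position with I_white ≤ I_dark is a hard error that names
the offending (line, pixel, band): calibration frames are controlled inputs
and silent masking would hide instrument faults. The identity is invariant
to a common positive rescaling of all three inputs.

Per-sample spectra are arithmetic ROI means over boolean pixel masks. Band
trimming keeps the closed interval [930, 1700] nm; on a uniform
874–1734 nm / 256-band grid this retains 228 band centers. Instruments with
non-uniform band tables can retain a different count (229 is common); the
package computes the count from the grid rather than forcing a target, and
the window endpoints are included by choice (documented, not tunable by the
trim itself).

## Synthetic scenes

The generator emulates the study layout: 7 roast-degree classes × 75
samples (525 total), each sample a dish of ~30 elliptical beans, imaged
over 256 bands with dark ≈ 100 and white ≈ 4000 counts (arbitrary fixed
sensor scale). Class signatures share a smooth quadratic baseline with
negative Gaussian absorption features at 940, 1210, 1350, 1450 and 1660 nm
(the C–H/O–H overtone regions of fat and water); the 1210 nm valley depth
increases monotonically with roast degree (0.06 → 0.15 reflectance units)
and a broad contrast lobe centred at 1140 nm (amplitude ±0.09) concentrates
between-class separation in 930–1350 nm, darker roasts reflecting less.
Noise is independent Gaussian per pixel per band in reflectance units
(default SD 0.004 inside the 930–1700 nm working range) and 10× larger at
the detector edges, modelling the noisy band margins; the 10× ratio is this
package's choice, as is every absolute effect size — the source study
published no per-class reflectance magnitudes, so the synthetic effect
sizes are exposed as configuration and are not claimed to match any
instrument.

The forward model is the exact inverse of the calibration equation, so a
noiseless scene → calibrate → extract round trip reproduces the class
signatures to ~1e−15, and a fast path (`generate_spectra_matrix`) draws
ROI-mean spectra directly with per-band SD = pixel SD/√(ROI pixels).

What the scenes do **not** model: optical scattering, illumination
geometry, bean-to-bean chemical variability within a class, spatial noise
correlation, and spectrograph smile/keystone. Passing tests therefore show
the *procedures* are correct and statistically well behaved, not that any
particular accuracy would be attained on real cubes.

### Planted-band benchmark

Selector validation uses 525 × 100 spectra in which 5 bands are informative
and 95 are pure noise (SD 0.01). Planted band k carries the pattern
(linear roast trend + orthogonal polynomial contrast k)/√2 at amplitude
0.08 RMS: every planted band is individually predictive of the ordinal
response, yet none is redundant given the others — the best k-band linear
model explains a fraction k/(k+1) of the trend variance, so a forward or
subset-search selector genuinely gains from retaining all five. This is the
scenario in which "recovering the informative bands" is well defined.

## Kennard–Stone partitioning

Classic max–min design on trimmed, unpreprocessed reflectance with
Euclidean distance: seed with the two most distant rows, then repeatedly
add the row whose minimum distance to the selected set is largest, until
round(cal_fraction·n) rows are chosen (350 of 525 at 2:1). Ties break to
the lowest row index; the procedure contains no randomness. A per-class
variant is provided; the global split is the default.

## PCA and PLS1

PCA is a column-mean-centred SVD; the sign of each loading is fixed so its
largest-magnitude element is positive, making loading plots reproducible.
Explained-variance fractions are relative to the total variance. PLS1 is
the NIPALS recursion on centred X and y; with the full latent dimension it
reproduces ordinary least squares, which the tests exploit as an oracle.
Class labels enter selection as ordinal dummy numbers 1…7 in roasting
order — the ordinal encoding respects the physical ordering of roast
degrees.

## Wavelength selectors

**X-loading**: "large absolute loading" is operationalized as local extrema
of the |loading| curves of the first components (endpoints included),
pooled across components with each band counted once at its largest
magnitude, then truncated to the n largest. If fewer extrema exist than
requested the result is flagged rather than padded.

**SPA**: chains are built on the calibration rows by modified Gram–Schmidt
deflation — at each step every remaining column is projected onto the
orthogonal complement of the chosen set and the column of maximal residual
norm is taken. Each chain (one per possible starting band) is scored by the
RMSE of a multiple linear regression predicting the dummy response on a
held-out third of the rows (a deterministic Kennard–Stone row split, chosen
because the source procedure names no validation scheme); the best chain is
returned in selection order. Degenerate projections truncate the chain and
flag the result.

**Random frog**: each of n_runs independent runs performs T iterations of
subset proposal and acceptance. The candidate dimension is drawn from
N(current size, (θ·size)²) with a proposal-SD floor of one band — without
the floor the dimension walk freezes once θ·size < 1 and the chain gets
absorbed at trivial subsets. Growth samples an ω-fold candidate pool from
the complement, refits the inner PLS1 on the union and keeps the top
candidate bands; shrinkage drops the least important members. Importance
for both moves is the **standardized** PLS coefficient (|coefficient| ×
band SD, i.e. the coefficient on autoscaled variables): raw coefficients
scale inversely with band SD, which would let tiny-variance bands with
chance correlations outrank genuinely informative ones. Candidates are
accepted with probability min(η, RMSE_current/RMSE_candidate), where RMSE
is 5-fold cross-validated inner-PLS RMSE on folds fixed per run (paired
comparisons); the inner latent count is min(10, subset size, n−1). SP_i is
the fraction of retained subsets containing band i, averaged over runs.
Defaults are T = 10000, Q = 50, θ = 0.3, ω = 3, η = 1, 50 runs; tests and
the acceptance script run the documented reduced profile T = 1000, 5 runs.

With η = 1 the acceptance rule is deliberately permissive (the stationary
distribution over subsets is only mildly peaked), so SP separates
informative from uninformative bands by ranking rather than by a sharp
threshold — consistent with published SP curves, where most bands sit at
low but non-zero probability. The number of bands kept (7/5/8 for
X-loading/SPA/random frog) is a parameter, not an inferred threshold.

## LS-SVM

One-vs-one multiclass wrapping (21 binary machines for 7 classes), each a
direct dense solve of the KKT system; majority vote with ties broken by
summed decision values. γ is searched pointwise on a log grid over
[1, 1000] (100 points by default, 20 in the reduced profile) by stratified
k-fold CV accuracy, ties resolving to the smallest γ then smallest σ². σ²
defaults to the median pairwise squared distance of the calibration rows
(median heuristic) — the source procedure tunes only γ and never reports
either value, so σ² handling is this package's addition. Stratified folds
come from scikit-learn's StratifiedKFold, seeded.

## Evaluation

Confusion matrices are integer count tables (rows = true class, columns =
predicted, classes in roasting order RD-U … RD-D); overall accuracy is
trace/n. The package ships the published reference matrices of the
roast-degree experiment as worked-example fixtures; their printed
percentage accuracies (89.80/88.70/90.30%) differ slightly from the ratios
implied by their own integer counts (157/175 = 89.71%, 155/175 = 88.57%,
158/175 = 90.29%). The integer counts are treated as authoritative and the
package reports exact ratios; the source of the percentage mismatch is
unknowable from the published tables.

A small empirical note: 10-fold CV accuracy on label-shuffled balanced data
sits slightly *below* the 1/7 chance level (≈12% in the acceptance run).
This is the well-known pessimistic bias of cross-validation under label
permutation — stratified training folds are anti-correlated with their test
folds — and the sanity check uses a tolerance that accommodates it.

## Problem sizes and profiles

Unit tests run on scaled-down scenes (2–15 samples per class, reduced
random-frog iteration counts); the study-scale 525-sample matrix is used
where the check is about layout (generator counts, 350/175 split) and for
the planted-band benchmark. The "full" profile (T = 10000, 50 runs,
100-point γ grid) is exposed through configuration for real analyses.

## Known limitations

* ENVI I/O covers BIL interleave with little-endian int16/uint16/float
  data — the subset the pipeline writes — not the full ENVI dialect.
* No spectral preprocessing (SNV, derivatives, smoothing) is implemented,
  mirroring the source workflow, so the package is not a general
  chemometrics preprocessing toolbox.
* The multiclass scheme is one-vs-one only; one-vs-rest would require a
  small extension of the model container.
* Random-frog SP values are Monte-Carlo estimates; at the reduced profile
  they carry visible run-to-run variance and only their ranking should be
  interpreted.
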