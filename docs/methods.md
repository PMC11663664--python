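# Methods

This note documents the models and numerical choices behind `peachem`:
what the synthetic generator emulates, how each pipeline stage is defined,
which parameters matter, and what the test suite does and does not
demonstrate about real spectra.

## Synthetic composition tables

The generator targets the descriptive statistics of a real pea sample set:
eleven variables (five chemical components in g/100 g or %, three seed
dimensions in mm, 100-seed weight in g, and two ordinal 1–4 scores for
seed shape and color), each with a mean, standard deviation and observed
range, plus thirteen reported pairwise Pearson correlations (for example
starch–moisture −0.53, protein–fiber 0.64, protein–fat 0.66). Unreported
pairs are set to zero — the least-informative fill — and the assembled
matrix is repaired to the nearest positive-semidefinite correlation matrix
by eigenvalue clipping (floor 1e−8) with diagonal renormalization,
iterated to convergence.

Sampling is a range-truncated correlated Gaussian: latent multivariate
normal vectors are drawn via Cholesky factorization and any vector with a
coordinate outside its variable's observed range is rejected and redrawn.
Ordinal scores are sampled as continuous latents on the 1–4 scale and
rounded to the nearest level (cuts at 1.5/2.5/3.5), which preserves the
reported non-uniform category means (1.97, 1.60) — equal-probability
quartile cuts would force a mean of 2.5.

Truncation, joint rejection and discretization all attenuate moments and
correlations, so the latent parameters are calibrated before the final
draw: ten iterations, each drawing a 6,000-row pilot sample, shifting the
latent means by 0.8× the observed mean error and inflating the latent
correlations multiplicatively toward their targets (damping 0.7, factors
clipped to [0.6, 1.67], entries to ±0.97, PSD-repaired each round). The
latent means start from the univariate truncated-normal solution (Brent's
method on the truncated mean). At n = 2000 the realized statistics land
within ±0.05 of each target correlation and within ±0.1 sd of each mean.
The calibration and the final draw consume separate seeded substreams, so
results are bit-reproducible for a fixed seed. A spec whose joint
acceptance rate falls below 1% is rejected as infeasible.

## Synthetic spectra

Spectra live on the instrument grid 908 + 6k nm, k = 0..128 (129
channels). Each chemical component has a pure spectrum built from Gaussian
bands, amp·exp(−4 ln2 (λ−c)²/w²), at its characteristic NIR wavelengths:
moisture 952/1280 nm (O–H overtones), crude fat 927/1181/1212/1243 nm
(C–H, CH₂, HC=CH), crude protein 1125/1428 nm (C–H, N–H), starch
952/1125/1385 nm (O–H/C–H combinations), crude fiber 1280/1385 nm. Band
width defaults to 60 nm FWHM (the centers are known; widths are a modeling
choice typical of NIR overtone bands). The first-listed band of each
component is its strongest; secondary bands carry 60% of its amplitude,
and amplitudes are normalized so a sample at mean composition contributes
about 0.5 absorbance per component — comparable dynamic range for all
five.

The noiseless spectrum is the concentration-weighted mixture (Beer–Lambert
in absorbance). Instrumental artifacts are then applied per sample:
multiplicative scatter A′ = (1+b)A + a with b ~ N(0, 0.005²),
a ~ N(0, 0.02²); a quadratic baseline with coefficient sds 0.005 on a
[−1, 1]-scaled wavelength axis; and i.i.d. channel noise with sd 3e−4
absorbance. The multiplicative slope deserves comment: it enters
*bilinearly* (slope × composition deviation), which no linear calibration
can fully remove, so its magnitude caps the achievable R². The defaults
are calibrated so the second-derivative starch model reaches calibration
R² ≈ 0.992–0.998 without saturating at 1.0; a slope sd of 0.05 would cap
it near 0.96 regardless of latent count. Scatter-correction comparisons in
the test suite deliberately raise the slope sd to 0.2 so that SNV/MSC
chains visibly beat raw spectra.

What the generator does *not* emulate: instrument temperature drift,
wavelength miscalibration, nonlinear detector response, band-shape
asymmetry, and any composition–scatter dependence (particle size
correlating with composition). Passing tests therefore demonstrate
correctness of the algorithms under a linear-mixture model with affine
artifacts, not field performance on real pea spectra.

## Preprocessing

The seven single methods are defined as: SNV — row-wise centering and
scaling by the sample sd (n−1); MSC — per-spectrum regression on a
reference (the calibration-set mean), then inversion (x−a)/b; detrend —
subtraction of the least-squares polynomial in wavelength (default order
2, computed on a scaled basis for conditioning); smoothing and derivatives
— Savitzky–Golay with window 11, polyorder 2 (raised to 3 for the second
derivative), derivatives scaled by (1/Δλ)^deriv with Δλ = 6 nm so
magnitudes are grid-independent, edges handled by the terminal polynomial
fit; normalization — unit Euclidean row norm; baseline — row-minimum
subtraction. The last two are named-but-undefined methods in common NIR
practice; these readings are the package's own definitions.

Chains hold up to four steps applied left to right. MSC is the only
stateful step: its reference is fitted on calibration data and reused
unchanged on validation data, so validation spectra never influence the
transform. The chain search space is the empty chain, all seven singles,
the two known-good derivative composites (1st+2nd, 1st+2nd+detrend), and
all ordered two-step combinations of {SNV, MSC, detrend, derivative1,
derivative2, smoothing} — 40 candidates after deduplication. Exhaustive
enumeration of four-step chains would be exponential and adds little.
Each candidate is scored by k-fold cross-validated PLS error (RMSECV) on
the calibration set at its own CV-selected latent count; ties break toward
fewer steps, then list order. Chains that fail on the data (for example
SNV on a constant spectrum) are recorded as failed rather than aborting
the search.

## Outlier rejection

PCA (column centering, SVD, no variance scaling) retains the smallest
number of components reaching 95% cumulative explained variance, capped at
n−2 so the score covariance is invertible. Mahalanobis distances on the
scores use the sample covariance (n−1); the mean squared distance then
obeys the closed form k(n−1)/n, which the tests exploit. Distances are
scaled by their maximum, and samples with scaled distance ≥ 0.5 are
flagged — the "half or more of the maximum" reading of the working
threshold; the scaling convention is a design choice, exposed as a
parameter. Removal drops flagged samples in descending distance order,
capped at 10 of 90 (≈11%) by default, because discarding too many samples
degrades the calibration more than retaining borderline ones. Detection
runs on raw spectra before any preprocessing.

## Partitioning

Canonical maximin Kennard–Stone on Euclidean distances: seed with the
globally farthest pair, then repeatedly add the candidate maximizing the
minimum distance to the selected set; ties break toward the lowest row
index, making the split fully deterministic. The calibration fraction
defaults to round(0.75 n) — the 3:1 convention. Distances are computed on
raw spectra: the preprocessing chain is itself selected on the calibration
set, so splitting on preprocessed spectra would be circular; splitting
first, on X only, also guarantees that validation chemistry can never
influence model construction (verified by a leakage test).

## PLSR

NIPALS PLS1, one component at a time (matching per-component reporting):
w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflation of both
blocks, regression vector b = W(PᵀW)⁻¹q. Successive scores are mutually
orthogonal; with latent count equal to rank(X) the predictions coincide
with ordinary least squares, and both properties are tested, the latter
against a pseudo-inverse oracle and scikit-learn's implementation.

The latent count (max 15) is chosen by seeded k-fold cross-validation
(default 10 folds, fold assignment by seeded permutation): SECV — the
bias-corrected sd of CV residuals — is computed per candidate count, and
the smallest count within 2% of the minimum SECV is selected. The 2%
parsimony band avoids chasing noise-level improvements with extra factors;
on pure-noise responses it selects one latent variable, and on data with
three planted spectral factors it selects three or four.

Metrics follow the standard multivariate-calibration definitions:
RMSE = sqrt(SSE/n) per set; R² = 1 − SSE/SST against each set's own mean
(coefficient of determination, not squared Pearson — the two differ when
predictions are biased, and the choice is documented for users comparing
conventions); RPD = sd(y)/RMSE with the n−1 sd, RMSE in the denominator
(SEP is reported separately rather than folded into RPD); SEC/SEP =
bias-corrected standard errors (n−1); bias = mean validation residual.
A perfect fit would make RPD infinite; it is reported as the sentinel 1e6.

## Statistics and grading

Descriptive statistics report min/max, mean, SE = sd/√n, sd,
CV = sd/mean and linearly interpolated quartiles. Pearson correlations
carry two-sided p-values from t = r√((n−2)/(1−r²)) on t(n−2), with
0.05/0.01 significance stars; zero-variance columns yield missing entries.
The biplot PCA standardizes variables (correlation-matrix PCA) because the
units are heterogeneous (mm, g, %, ordinal); loadings are scaled by the
singular values so arrow length tracks explained variance, and pairwise
loading angles come from the normalized 2-D loading dot product.

Variety clustering is K-means (k-means++ initialization, 10 seeded
restarts, best inertia kept; a restart producing an empty cluster is
discarded) on the five standardized chemical components only — the sensory
variables describe the seed, not its processing value. For k = 3 the
clusters are named by centroid: lowest mean fat → low-fat; of the rest,
higher mean starch → high-starch; the other → high-protein.

Grading maps each sample to a level triple with half-open intervals,
resolving shared boundary values toward the better grade: fat ≤5 → 1,
(5,9) → 2, ≥9 → 3; starch ≥55 → 1, [45,55) → 2, <45 → 3; protein ≥25 → 1,
[20,25) → 2, <20 → 3 (g/100 g). The mapping is total and deterministic
for any finite nonnegative composition.

## Pipeline and reproducibility

The run order is simulate (or load CSVs) → PCA-Mahalanobis outlier removal
→ Kennard–Stone split → per-component chain search on the calibration set
→ PLSR fit and evaluation (raw baseline and best chain) → clustering and
grading. All randomness derives from one root seed through named
substreams (CRC-mixed into a `SeedSequence` per stage), so changing, say,
the candidate chain list never shifts the generator stream, and a rerun
with the same config is byte-identical. Problem sizes follow the study
conditions throughout: 90 generated samples, up to 10 removals, 60/20
split, n = 2000 for the statistical recovery checks — small enough that
the full suite runs in well under a minute of compute per heavy test.

## Known limitations

- The spectral model is linear-mixture with affine artifacts; real NIR
  spectra of intact seeds include path-length and particle-size effects
  correlated with composition.
- The bilinear scatter term bounds achievable R² from above; reported
  synthetic performance is therefore a function of the chosen artifact
  magnitudes, not evidence about any particular instrument.
- The chain search covers at most the enumerated 40 candidates; longer
  bespoke chains must be passed explicitly.
- Mahalanobis scaling by the sample maximum makes the 0.5 threshold
  relative; a batch with no true outliers will still flag its most extreme
  samples (the removal cap is the safeguard).
- K-means cluster naming assumes the three archetypes are present; on
  degenerate compositions the name assignment is still total but not
  meaningful.
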