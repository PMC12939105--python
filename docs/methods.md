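# Methods

This note documents the models and procedures implemented in `radpdl1`,
their assumptions, the numerical conventions behind them, and what the
synthetic test conditions do and do not establish.

## Imaging model and preprocessing

The unit of input is a 3D CT sub-volume in Hounsfield units with an aligned
binary lesion mask; segmentation itself is out of scope (masks are inputs).
Because texture statistics are defined on voxel neighbourhoods, volumes are
first resampled to isotropic 1×1×1 mm voxels — trilinear interpolation for
intensities, nearest-neighbour for masks followed by re-binarization, the
standard convention when no interpolator is otherwise mandated. Intensities
are then truncated to the lung window (level −600 HU, width 1500 HU) and
cropped to the lesion bounding box with a 2-voxel margin. The order is
resample → window → crop, and features are computed on the windowed
intensities. All modules share the (x, y, z) axis convention with per-axis
spacing.

## Filter bank

Fifteen size-preserving response images per lesion:

- **LoG**: Laplacian-of-Gaussian at σ = 0.1, 0.5, 1, 2, 3, 4, 5 mm,
  interpreted in millimetres on the 1 mm grid. The implementation is
  separable (second-derivative-of-Gaussian along one axis, Gaussian along
  the others) with an explicitly DC-corrected derivative kernel: the
  truncated discrete kernel is projected to zero sum along the Gaussian, so
  constant and linear images produce an exactly zero interior response
  rather than a small truncation bias.
- **Wavelet**: a single-level undecimated separable 3D decomposition into
  all 8 H/L per-axis combinations, Coiflet-1 basis by default. Undecimated
  (size-preserving) filtering keeps every subband aligned with the mask,
  which is what lets first-order and texture features be read under the
  original ROI. Subband labels concatenate per-axis choices in x, y, z
  order (HHL = high-pass x and y, low-pass z).

Boundary handling is edge replication for both families. Because the
Coiflet-1 filters have even length, mirroring an image mirrors the subbands
only up to a one-voxel origin offset; the symmetry test accounts for this.

## Radiomics features

1409 features per lesion under the default configuration, named
`<filter>_<family>_<feature>`:

- 14 shape features from the original mask only;
- per filtered image, 18 first-order + 75 texture features
  (24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM), giving 93 × 15 = 1395;
- totals: 7·93 = 651 LoG-derived, 8·93 = 744 wavelet-derived,
  651 + 744 + 14 = 1409, with 270 first-order and 1125 texture features.

This family taxonomy is the standard radiomics set and is the unique
decomposition consistent with all the printed counts simultaneously; shape
on the original image only (and first-order/texture on filtered images
only) is forced by the 651 + 744 + 14 arithmetic.

Numerical conventions, all enforced by tests against independent
brute-force enumeration oracles:

- **Discretization**: fixed bin width (default 25 HU) anchored at the ROI
  minimum, `level = floor((x − min)/w) + 1`, applied to filtered responses
  as well; min-anchoring makes every texture feature invariant to constant
  intensity offsets.
- **GLCM/GLRLM**: distance-1, the 13 unique 3D directions, symmetric
  matrices, features computed per direction and averaged.
- **GLSZM zones and GLDM/NGTDM neighbourhoods**: 26-connectivity; GLDM
  dependence = 1 + number of neighbours within `alpha` (default 0) levels.
- **Degenerate values** are finite by convention: single-level GLCM has
  Correlation = MCC = 1 and Imc1 = Imc2 = 0; NGTDM coarseness of a flat ROI
  is capped at 10⁶; entropies skip empty cells (log₂).
- **Sparse matrices**: all texture matrices are held as occupied-cell
  triplets and the feature formulas operate on those triplets, so cost
  scales with voxel count rather than (gray levels)² — filtered images can
  legitimately span thousands of levels at a fixed 25 HU bin width. The
  GLCM maximal correlation coefficient uses dense eigendecomposition up to
  64 occupied levels and a matrix-free Arnoldi solve (fixed start vector,
  hence deterministic) above that, exploiting that the MCC kernel is
  row-stochastic with leading eigenvalue 1.
- **Shape**: marching-cubes triangulation at iso-level 0.5 of the padded
  mask for surface area and (divergence-theorem) mesh volume; axis lengths
  are 4·√λ of the voxel-coordinate covariance eigenvalues, with
  elongation √(λ₂/λ₁) and flatness √(λ₃/λ₁); single-voxel masks fall back
  to voxel-cube geometry. Sphericity = (36π V²)^⅓ / A.
- **First-order**: population moments; skewness and kurtosis are 0 for a
  constant ROI; kurtosis is non-excess; entropy/uniformity use the fixed
  bin-width discretization.

## Selection and classifier

Standardization (zero mean, unit SD) is fitted on training rows only;
columns constant on the training set are dropped with a logged warning.
Feature selection is L1-penalized logistic regression over a 30-point
log-spaced penalty grid from the KKT bound λ_max (empty support) down three
decades, scored by 5-fold stratified cross-validated binomial deviance
restricted to the training partition. The chosen penalty follows the
**one-standard-error rule** — the largest λ whose mean CV deviance is
within one SE of the minimum. The plain deviance minimizer was measured to
select ~21 features on the sparse recovery benchmark (n = 500, p = 100,
k = 5, |β| = 1) where the parsimony expectation is ≤ 15; the 1-SE rule
recovers 5/5 planted features with a median support of ~10 and is the
standard sparse choice, so it is the default. The support and coefficients
are frozen after fitting.

The classifier is a feature-tokenizer transformer: token_j = x_j·W_j + b_j
with a learned CLS token appended (k + 1 tokens of width d), pre-norm
blocks of multi-head self-attention and a GELU feed-forward (residual
around both), a final layer-norm, and a linear head on the CLS state with
sigmoid output. Defaults: d = 64, 3 layers, 4 heads, FFN multiplier 4,
dropout 0.1, Adam at 1e-4, batch 32, ≤ 200 epochs with early stopping
(patience 20) on a stratified 15% validation split of the training rows.
These hyperparameters are declared defaults exposed in the config, not
tuned claims. The implementation is pure NumPy with hand-derived
reverse-mode gradients; a finite-difference check in the test suite holds
to ~1e-7 relative error. Inference is deterministic; dropout and batch
order derive from the configured seed, so identical seeds give bit-identical
weights.

## Self-training

One round by default: supervised training on the labeled set, scoring of
the unlabeled pool, pseudo-labels for instances with p ≤ τ_lo or p ≥ τ_hi
(defaults 0.2 / 0.8 — the band between is where classifier errors
concentrate), then fine-tuning (continued optimization, learning rate
× 0.1) on labeled ∪ pseudo-labeled with unit pseudo-label weight.
Patient-id disjointness between labeled, unlabeled and test pools is
asserted before any fitting; overlap is a hard error. An empty pool or an
empty gate result degrades to the supervised model.

## Evaluation

AUC is the Mann–Whitney statistic (ties ½). Confidence intervals are
percentile bootstrap over 2000 patient-level resamples (resamples losing a
class are skipped and logged); the method is a reporting choice, not an
inferential claim. The operating point is the largest threshold achieving
the target sensitivity (default 0.7) on the **training** scores, frozen
before test evaluation — choosing it on test data would leak. Calibration
uses 10 equal-width bins and the Brier score; isotonic recalibration
(pool-adjacent-violators via scikit-learn) is fitted on training
predictions and applied out-of-sample, with a CV-fit alternative behind the
API. Group separation is reported as a two-sided Mann–Whitney p (exact for
small groups) and Cohen's d with the pooled-SD convention.

## Attribution and decision curves

Shapley values are estimated by permutation sampling on the model's
probability output: per round, a random feature order and a random
background row; walking the order from background to instance values
assigns marginal contributions, with the reversed order included as an
antithetic pair. The base value is the mean model output over the drawn
background rows, which makes the efficiency identity
Σφ + base = f(x) exact up to floating point (the residual is reported).
Features are ranked by mean |φ| with a deterministic lexicographic
tie-break; signed means are reported alongside because the sign carries the
direction of the association. Rank stability is the mean ± SD of pairwise
Spearman correlations across partitions.

Net benefit at threshold probability p_t is TP/N − (FP/N)·p_t/(1 − p_t)
with the score dichotomized at p_t itself; treat-all is
π − (1 − π)·p_t/(1 − p_t) and treat-none is 0. The default grid is
0.01–0.99 in steps of 0.01, with the clinically highlighted 0.25–0.68 band
marked on plots.

## Survival

The score cutoff is selected on training data only by scanning observed
score quantiles and maximizing the log-rank statistic subject to both
groups holding ≥ 10% of patients — an open emulation of the proprietary
cutoff-scan software, then frozen. Kaplan–Meier estimation, the log-rank
test and Cox proportional-hazards regression go through lifelines; ties use
Efron's method (better than Breslow at monthly granularity), CIs are Wald,
and a scaled Schoenfeld-residual trend test is reported per covariate as
the proportional-hazards diagnostic. Exactly duplicated covariate columns
are rejected before fitting (silent collinearity is worse than an error).
The median survival convention is the first time with S(t) ≤ 0.5,
undefined when never reached.

## Synthetic data: what it emulates and what it does not

- `make_phantom`: an ellipsoidal lesion (air-like −900 HU background)
  whose interior is base HU plus `heterogeneity` × a unit-variance
  Gaussian-smoothed noise field (correlation length 2 mm). Heterogeneity is
  the controllable knob because the pipeline's interpretability analysis
  ties high scores to textural heterogeneity; a generator without that knob
  could not test the association.
- `make_cohort`: per-patient heterogeneity ~ Gamma(4, 10) (mean 40 HU);
  the binary label follows a logistic link in standardized heterogeneity
  with slope `label_effect` and an intercept calibrated to the requested
  prevalence. Covariate margins loosely mirror an advanced-NSCLC cohort
  (~51% male, ~29% current smokers, ~14% ECOG ≥ 2) and are cosmetic.
- `make_survival`: exponential event times with hazard λ₀·HR^label
  (baseline median 4 months, default HR 0.39 protective for the
  high-expression class) and independent Uniform(0, u) censoring with u
  solved analytically so the expected censored fraction matches the
  request.
- `make_semisup_benchmark`: two Gaussian clusters in 20 dimensions at
  separation 2.5 (distance between class means), 60 labeled / 600
  unlabeled / 400 test. The dimensionality and separation were fixed once
  on the structural argument that a 60-sample supervised fit must be
  variance-dominated while cluster cores remain confidently and accurately
  pseudo-labeled — the regime in which self-training helps.

Phantoms are not lungs: no anatomy, no scanner noise model, no partial
volume at real acquisition resolutions, single lesion per patient, sharp
lesion boundary. Passing tests therefore establish internal correctness
and the qualitative behaviours (count identities, parameter recovery,
self-training benefit, leakage safety) — not clinical performance on
patient data, which would require the original cohorts.

## Problem sizes and determinism

Test and acceptance runs use scaled problem sizes chosen as the package's
own benchmark conditions: 32³ phantom grids, a compact transformer
(d = 32, 2 layers) for multi-seed benchmarks, 20 seeds for recovery and
self-training statistics, 10 for null checks. Every stochastic component
(generators, splits, training, bootstrap, SHAP) takes an explicit seed and
is bit-reproducible given it.

## Known limitations

- Texture conventions (bin width, distance set, aggregation) follow the
  dominant radiomics defaults; original-study feature values cannot be
  reproduced bit-for-bit because those settings are not fully specified
  anywhere, so conformance is defined by counts, invariants and oracles.
- The transformer is small-data oriented; no GPU path exists and very wide
  feature sets (no LASSO stage) would be slow.
- Isotonic recalibration on small test sets is high-variance; the Brier
  comparison is only guaranteed non-increasing on the fit set.
- The cutoff scan maximizes the log-rank statistic and therefore inherits
  the optimism of maximally selected statistics; it is deliberately
  restricted to training data and reported as such.
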