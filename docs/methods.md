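# Methods

This note records the statistical model behind `ftirclass`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Problem setting

The package targets binary diagnosis from one-dimensional absorbance
spectra of biofluids (FTIR transmission spectra of dried plasma films,
and comparable modalities). Cohorts are small — tens of patients, three
replicate spectra per patient sample — while the feature dimension is
large (3301 wavenumbers on the default 700–4000 cm⁻¹ grid at 1 cm⁻¹).
Two consequences drive the design: every fitted statistic must come from
the training partition only, and train/test splits must operate on
*specimens* (patients), never on individual replicate spectra, because
replicates of one specimen are strongly correlated and splitting them
across a boundary inflates accuracy estimates.

## Preprocessing

**Outlier flagging.** The scored statistic is each sample's total
absorbance; a sample is flagged when its absolute Z-score (sample sd,
ddof 1) exceeds `z_threshold` (default 3.0). A scalar summary per sample
is deliberate: it is scale-sensitive (catches deposition and path-length
artifacts) and trivially auditable. Note the algebraic bound
|z| ≤ (n−1)/√n for ddof-1 Z-scores: in cohorts of ≤ 9 samples a
threshold of 3 can never fire. Flagged samples are removed before model
fitting by default (`remove_outliers`), and the flags are recorded on
the fitted model either way. Flagging happens at train time only; test
samples are never dropped.

**ALSS baseline.** The baseline z of a spectrum y minimizes
Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σᵢ(Δ²zᵢ)², with wᵢ = p where yᵢ > zᵢ and 1−p
otherwise, weights re-estimated over `iters` iterations starting from
w ≡ 1. Defaults λ = 10⁵, p = 0.01, 10 iterations — canonical values for
this algorithm family at ~1 cm⁻¹ point spacing; all three are exposed in
the config. The normal equations (W + λD₂ᵀD₂)z = Wy are
symmetric penta-diagonal and solved with a banded Cholesky routine
(`scipy.linalg.solveh_banded`), O(n) per iteration; a dense-matrix
reference solver in the test suite confirms agreement to 10⁻⁸. Because
constants and straight lines span the null space of the second-difference
penalty, affine backgrounds are removed exactly (shift equivariance is
property-tested at 10⁻⁶). Spectra shorter than 3 points are rejected.

**Normalization.** "Batch normalization" in this (non-neural) pipeline
is per-wavenumber standardization with the training mean and ddof-1 sd.
Zero-variance columns are recorded with sd 0 and map to 0 on transform
rather than dividing by zero. The transform never touches test
statistics; this is property-tested by permuting test rows.

## Feature extraction

**PCA.** Components are the top-k eigenvectors of the sample (n−1)
covariance; the implementation delegates to a full SVD and enforces two
conventions on top: k ≤ min(n−1, d) (the covariance rank bound, stricter
than the SVD's n bound), and a fixed sign (each loading row's
largest-magnitude entry positive) so outputs are reproducible across
linear-algebra back-ends. Equivalence with a brute-force
eigendecomposition is tested on 50 random instances at 10⁻⁸.

**Component count.** k is the smallest count whose cumulative explained
variance reaches `variance_target` (default 0.999). If the target is
unreachable all components are kept, with a warning. An explicit `k`
overrides the rule (used by the PC sweep).

**Class-specific (dual) PCA.** One PCA per training class; every sample
is projected into both spaces label-blind and the two k-score blocks are
concatenated into 2k features, identically at train and test time. The
shared k comes from applying the variance rule to a *pooled* training
PCA, capped at the per-class rank bound min(n₀−1, n₁−1, d) — a single k
keeps the two blocks commensurate and matches how a single component
count is reported per dataset; per-class selection is available behind
`per_class_k`.

**LDA.** Closed form: direction ∝ S_w⁻¹(μ₁−μ₀) with the pooled
(unnormalized) within-class scatter S_w regularized by
10⁻⁸·tr(S_w)/m·I. The ridge matters: after dual PCA, 2k can exceed the
class counts inside small CV folds and S_w is then singular. The
direction is unit-norm, oriented so class 1 projects above class 0; the
threshold (midpoint of projected class means, equal priors) is recorded
but the downstream SVM learns its own cut.

## Classifier and search

The SVM uses inverse-frequency class weights in balanced mode (class c
weighted n/(2n_c)), appropriate for cohorts with more controls than
cases. The hyperparameter grid — kernel ∈ {linear, rbf},
C ∈ {0.1, 1, 10, 100}, γ ∈ {10⁻³, 10⁻², 10⁻¹, 1/(m·var(Z))} — is walked
in a fixed order (linear first, C ascending, γ in listed order with the
variance-scaled value last) and scored by stratified 5-fold internal CV
regardless of the outer scheme; ties keep the earliest, i.e. simplest,
configuration, so the chosen hyperparameters are bit-reproducible under
a fixed seed. A grid point whose internal training fold degenerates to
one class scores 0.5 (chance) for that fold with a warning rather than
crashing the search. The grid is intentionally small and is reported
with every fitted model so runs are comparable.

## Validation

All three schemes split by specimen and assert zero specimen leakage on
every run:

- **Leave-one-specimen-out:** one fold per specimen, that specimen's
  replicates as the test set, pipeline refit from scratch per fold.
  Because a three-replicate specimen yields three correlated test
  calls, a specimen-level majority-vote accuracy (ties toward the
  positive class) is reported alongside the sample-level pooled metrics.
- **Grouped stratified k-fold** (default 10): specimens partitioned,
  label-stratified where possible; per-fold and mean accuracies reported.
- **Repeated 80/20 holdout:** specimen-level splits, redrawn (bounded
  retries) until both classes appear on both sides; mean and sd of
  accuracy over repeats.

Metrics are computed on pooled confusion counts (positive class =
cancer = 1) with exact Clopper–Pearson 95% intervals from Beta
quantiles. Pooling sample-level counts across folds is the denominator
convention for the intervals; fold-level accuracies are also kept so
dispersion is visible. Fold assignments are fingerprinted, and the
comparison report runs every method on identical folds so method
differences are paired, not confounded with split luck.

Model selection (the variance rule and the hyperparameter grid) runs
inside each training fold, never on the full dataset — stricter than
selecting once globally, and the leakage-safe choice when in doubt.

## Synthetic data

The generator emulates the *statistical structure* of a biofluid FTIR
cohort, not its physics. A seed library of 15 surrogate "molecular
group" spectra — each a sum of 3–8 Gaussian bands, centers across the
grid, widths 8–60 cm⁻¹, heights 0.1–1, non-negative — stands in for
averaged libraries of isolated material spectra. For sample i of class c
and group j, a multiplier g_ij ~ N(μ_c, σ_c) is drawn independently and
the clean spectrum is Σⱼ bⱼ·g_ij·seedⱼ (base weights b default to 1).
Drawing one multiplier per sample–group pair, rather than one scalar per
sample, makes the classes differ in spectral *shape*, not just a global
scale. White Gaussian noise is added pointwise; the default level is 1%
of the class-0 mean clean spectrum's peak height. The three replicates
of a specimen share their g_ij and differ only in noise, mirroring
repeated measurements of one deposited sample. Defaults are
μ₀ = 1.00, μ₁ = 1.12, σ₀ = σ₁ = 0.05, 100 samples per class; with three
replicates per specimen the last specimen of each class carries the
remainder (one replicate at n = 100).

What this does **not** model: Beer–Lambert mixing nonlinearity, water
vapor and CO₂ lines, ATR penetration-depth dispersion, scattering
baselines beyond the smooth backgrounds ALSS removes, instrument drift
between sessions, or biological covariance between molecular groups. A
pipeline that is perfect here can still fail on real spectra; the
generator's role is controlled difficulty (the Δmean × Δsd contour
study), chance-level controls, and structural tests (span/recovery
properties, component-count sweeps).

One empirical caveat found while characterizing the generator: the
class-specific dual-PCA mode does not systematically beat pooled PCA on
this synthetic family — across several constructions, including classes
with disjoint high-variance group subsets, the two modes tie on average,
and under heavy white noise pooled PCA can win. That is consistent with
benchmark reports in which all methods perform comparably on synthetic
data, and it means any dual-vs-pooled advantage claimed for real spectra
should be established on real spectra.

## Problem sizes and determinism

The acceptance script evaluates five independently generated 200-sample
cohorts on the full 3301-point grid (≈ one minute on one CPU); the test
suite exercises end-to-end behavior on a 301-point sub-grid with reduced
classifier grids where the full setting adds cost without information,
and at full scale where the claim concerns the full setting. Every
source of randomness (generator, fold shuffling, internal CV) derives
from explicit integer seeds via `numpy.random.SeedSequence` spawn keys,
so stage seeds are decorrelated but reproducible; CLI runs write a
manifest (config, seed, version, input checksums) sufficient to rerun
bit-identically.

## Known limitations

- Binary classification only; no multiclass LDA or one-vs-rest SVM.
- No scatter correction (SNV/MSC), derivatives, or smoothing; no
  resampling onto the grid — inputs must already share a uniform grid.
- Sensitivity/specificity confidence intervals treat pooled replicate
  calls as independent trials; with three replicates per specimen the
  effective n is smaller and the intervals are somewhat anti-conservative
  (the specimen-level vote accuracy is reported for LOOCV as a check).
- The Z-score outlier rule is a gross-artifact guard, not a robust
  outlier detector.
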