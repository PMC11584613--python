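# ftirclass

Binary classification of one-dimensional biofluid FTIR spectra — for
example, distinguishing cancer from non-cancer patient plasma — with a
**class-specific (dual) PCA → LDA → SVM** pipeline, leakage-safe grouped
validation, exact binomial confidence intervals, and a synthetic-spectrum
generator so the whole method can be exercised and stress-tested without
patient data.

Intended users are chemometrics / clinical-spectroscopy researchers who
have a table of absorbance spectra (one row per measured sample, a shared
wavenumber grid, a few replicate measurements per specimen) and want a
reproducible, audited route from raw spectra to cross-validated
diagnostic accuracy.

## The method

Each spectrum `x ∈ R^d` (default grid 700–4000 cm⁻¹ at 1 cm⁻¹, d = 3301)
passes through:

1. **Outlier flagging** — a Z-score on per-sample total absorbance
   (|z| > 3 flags; flagged training samples are removed by default).
2. **Baseline correction** — asymmetric least squares smoothing (ALSS):
   the baseline `z` minimizes `Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σᵢ(Δ²zᵢ)²` with
   `wᵢ = p` above the baseline and `1−p` below, re-estimated each
   iteration (defaults λ = 10⁵, p = 0.01, 10 iterations). Constants and
   linear ramps lie in the penalty's null space and are removed exactly.
3. **Normalization** — per-wavenumber standardization using statistics of
   the *training* partition only.
4. **Class-specific PCA** — one PCA is fitted on each training class; any
   sample (train or test, label unseen) is projected into both principal
   spaces and the scores concatenated: `z = [P₀(x) | P₁(x)] ∈ R^{2k}`.
   The shared component count k is the smallest that retains 99.9% of the
   pooled training variance. Pooled single PCA and a no-PCA mode are
   available as baselines.
5. **LDA** — the Fisher discriminant `w ∝ S_w⁻¹(μ₁−μ₀)` (small ridge on
   `S_w`), reducing to one dimension.
6. **SVM** — maximum-margin classifier with class weights inversely
   proportional to class frequencies and a deterministic grid search over
   kernel ∈ {linear, rbf}, C ∈ {0.1, 1, 10, 100}, γ ∈ {10⁻³, 10⁻², 10⁻¹,
   1/(m·var)} scored by internal 5-fold CV.

Validation never lets the replicates of one specimen straddle a
train/test boundary: leave-one-specimen-out CV, specimen-grouped
stratified 10-fold CV, and repeated specimen-level 80/20 holdout are
provided, all with exact Clopper–Pearson 95% intervals on the pooled
counts.

The synthetic generator builds two-class datasets as noisy weighted sums
of 15 surrogate "molecular group" seed spectra, with per-class Gaussian
weight distributions `N(μ_c, σ_c)` whose mean/sd offsets dial class
separability from chance to perfect.

## Worked example

Generate a synthetic cohort at the standard class-mean offset of 0.12
(60 samples per class, 3 replicates per specimen) and evaluate the
dual-PCA pipeline under specimen-grouped 10-fold CV:

```bash
cat > demo.yaml <<'EOF'
seed: 42
synthesize:
  n_per_class: 60
EOF
ftirclass synthesize --config demo.yaml --out synth.csv
ftirclass evaluate --scheme kfold --config demo.yaml --spectra synth.csv --out report.json
```

which logs

```
INFO ftirclass: wrote 120 samples x 3301 points to synth.csv
INFO ftirclass: kfold accuracy 1.000 (CI 0.970-1.000)
```

i.e. at a 12% class-mean weight offset with 1% noise the classes are
fully separable: all 120 held-out predictions are correct, and the exact
95% Clopper–Pearson interval on 120/120 successes still spans down to
0.970 — a reminder of how wide exact intervals are at these cohort sizes.

At a harder operating point (6% offset, 25× the default noise) the
method-comparison matrix separates the pipelines. `ftirclass compare`
re-runs every method on *identical* fold assignments:

```
     method pca_mode  accuracy  sensitivity  specificity  accuracy_ci_low  accuracy_ci_high
    lda_svm     none     0.833        0.867        0.800            0.754             0.895
    pca_svm   single     0.833        0.883        0.783            0.754             0.895
    pca_svm     dual     0.575        0.550        0.600            0.481             0.665
pca_lda_svm   single     0.833        0.867        0.800            0.754             0.895
pca_lda_svm     dual     0.583        0.883        0.283            0.490             0.673
```

Which feature mode wins is condition-dependent on synthetic data (here
heavy white noise favors pooled PCA); the generator exists precisely to
map out such regimes, e.g. with `ftirclass contour` (accuracy over a
Δmean × Δsd grid) and `ftirclass sweep-pcs` (accuracy vs component
count).

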