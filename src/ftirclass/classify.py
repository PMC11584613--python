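"""Margin classifier with grid search, and end-to-end pipeline composition.

The pipeline fits strictly in order on training data only:
outlier removal -> ALSS baseline correction -> normalization ->
feature mode (pooled PCA | class-specific dual PCA | none) ->
optional LDA -> SVM with grid-searched hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import features as feat
from . import preprocess as prep
from .spectra_io import SpectrumSet


@dataclass
class ClassifierSpec:
    """Hyperparameter grids for the margin classifier.

    The grid is walked in a fixed order (linear before rbf, C ascending,
    gamma in listed order with "scale" last) and ties in internal CV
    accuracy keep the earliest — hence simplest — configuration, so the
    chosen hyperparameters are bit-reproducible.
    """

    kernels: tuple = ("linear", "rbf")
    C_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = (1e-3, 1e-2, 1e-1, "scale")  # "scale" = 1/(m*var(Z))
    class_weight_mode: str = "balanced"              # "balanced" | "none"

    def __post_init__(self) -> None:
        if not self.kernels or not self.C_grid:
            raise ValueError("kernel and C grids must be non-empty")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("C values must be > 0")
        if any(g != "scale" and g <= 0 for g in self.gamma_grid):
            raise ValueError("gamma values must be > 0")
        if "rbf" in self.kernels and not self.gamma_grid:
            raise ValueError("rbf kernel needs a non-empty gamma grid")
        if self.class_weight_mode not in ("balanced", "none"):
            raise ValueError(f"unknown class_weight_mode {self.class_weight_mode!r}")

    def grid_points(self):
        for kernel in self.kernels:
            for c in self.C_grid:
                if kernel == "linear":
                    yield {"kernel": "linear", "C": c}
                else:
                    for g in self.gamma_grid:
                        yield {"kernel": kernel, "C": c, "gamma": g}


def _make_svc(params: dict, spec: ClassifierSpec) -> SVC:
    cw = "balanced" if spec.class_weight_mode == "balanced" else None
    return SVC(class_weight=cw, **params)


def train_classifier(z: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                     cv_folds: int = 5, seed: int = 0):
    """Exhaustive grid search by internal stratified k-fold accuracy.

    Returns (fitted SVC refit on all of z, chosen params, search table).
    Balanced mode weights class c by n / (2 * n_c).  A grid point whose
    training fold degenerates to a single class is scored as chance (0.5)
    for that fold, with a warning.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("classifier training needs exactly 2 classes")
    n_splits = min(cv_folds, int(counts.min()))
    if n_splits < 2:
        raise ValueError("minority class too small for internal CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(z, y))

    best_score, best_params = -np.inf, None
    table = []
    for params in spec.grid_points():
        scores = []
        for tr, te in folds:
            if np.unique(y[tr]).size < 2:
                warnings.warn("single-class internal fold; scoring as chance")
                scores.append(0.5)
                continue
            clf = _make_svc(params, spec).fit(z[tr], y[tr])
            scores.append(clf.score(z[te], y[te]))
        score = float(np.mean(scores))
        table.append({**params, "cv_accuracy": score})
        if score > best_score:  # strict: earlier (simpler) grid point wins ties
            best_score, best_params = score, params
    best = _make_svc(best_params, spec).fit(z, y)
    return best, dict(best_params), table


@dataclass
class PipelineConfig:
    """All tunable settings of the classification pipeline."""

    # preprocess
    z_threshold: float = 3.0
    remove_outliers: bool = True
    alss_lambda: float = 1e5
    alss_p: float = 0.01
    alss_iters: int = 10
    normalize: bool = True
    # features
    feature_mode: str = "dual_pca"        # "single_pca" | "dual_pca" | "none"
    variance_target: float = 0.999
    k: int | None = None                  # overrides the variance rule
    per_class_k: bool = False             # dual mode: select k per class
    use_lda: bool = True
    # classifier
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    inner_cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.feature_mode not in ("single_pca", "dual_pca", "none"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")


@dataclass
class PipelineModel:
    """Fitted pipeline state; predict refuses an unfitted model."""

    config: PipelineConfig
    preprocess: prep.PreprocessModel
    features: feat.PCAModel | feat.DualPCAModel | None
    lda: feat.LDAModel | None
    svc: SVC
    chosen_params: dict
    rng_seed: int
    outlier_flags: np.ndarray
    fitted: bool = False

    def _featurize(self, s: SpectrumSet) -> np.ndarray:
        """Label-blind application of every fitted stage before the SVM."""
        cfg = self.config
        x = prep.alss_correct_matrix(s.absorbance, cfg.alss_lambda, cfg.alss_p,
                                     cfg.alss_iters)
        if cfg.normalize:
            x = prep.apply_normalizer(self.preprocess, s.with_absorbance(x)).absorbance
        if isinstance(self.features, feat.DualPCAModel):
            x = feat.transform_dual(self.features, x)
        elif isinstance(self.features, feat.PCAModel):
            x = self.features.transform(x)
        if self.lda is not None:
            x = feat.transform_lda(self.lda, x)
        return x

    def predict(self, s: SpectrumSet) -> np.ndarray:
        if not self.fitted:
            raise ValueError("pipeline is not fitted")
        if self.config.normalize and s.n_points != self.preprocess.norm_mean.size:
            raise ValueError("grid mismatch between model and data")
        return self.svc.predict(self._featurize(s))

    def decision_function(self, s: SpectrumSet) -> np.ndarray:
        if not self.fitted:
            raise ValueError("pipeline is not fitted")
        return self.svc.decision_function(self._featurize(s))


def _select_shared_k(x: np.ndarray, y: np.ndarray, cfg: PipelineConfig) -> int:
    """Shared dual-PCA k from the variance rule on a pooled-training PCA,
    capped at the per-class rank bound."""
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    kcap = min(n0 - 1, n1 - 1, x.shape[1])
    pooled = feat.fit_pca(x, variance_target=cfg.variance_target)
    return min(pooled.k, kcap)


def fit_pipeline(train: SpectrumSet, config: PipelineConfig | None = None,
                 seed: int = 0) -> PipelineModel:
    """Fit every stage, in order, on the training partition only."""
    cfg = config if config is not None else PipelineConfig()
    s = train
    if np.any(s.labels < 0):
        raise ValueError("training set contains unlabeled samples")

    # outlier removal (train-time only; flags recorded on the model)
    flags = prep.flag_outliers(s, cfg.z_threshold)
    if cfg.remove_outliers and flags.any():
        s = s.select(~flags)

    pm = prep.PreprocessModel(z_threshold=cfg.z_threshold, alss_lambda=cfg.alss_lambda,
                              alss_p=cfg.alss_p, alss_iters=cfg.alss_iters)
    x = prep.alss_correct_matrix(s.absorbance, cfg.alss_lambda, cfg.alss_p, cfg.alss_iters)
    if cfg.normalize:
        pm = prep.fit_normalizer(x, pm)
        x = prep.apply_normalizer(pm, s.with_absorbance(x)).absorbance
    y = s.labels

    fmodel = None
    try:
        if cfg.feature_mode == "single_pca":
            fmodel = (feat.fit_pca(x, k=cfg.k) if cfg.k is not None
                      else feat.fit_pca(x, variance_target=cfg.variance_target))
            z = fmodel.transform(x)
        elif cfg.feature_mode == "dual_pca":
            if cfg.per_class_k and cfg.k is None:
                sub = {c: feat.fit_pca(x[y == c], variance_target=cfg.variance_target)
                       for c in (0, 1)}
                fmodel = feat.DualPCAModel(pca0=sub[0], pca1=sub[1])
            else:
                k = cfg.k if cfg.k is not None else _select_shared_k(x, y, cfg)
                fmodel = feat.fit_dual_pca(x, y, k)
            z = feat.transform_dual(fmodel, x)
        else:
            z = x
    except ValueError as e:
        raise ValueError(f"feature stage failed: {e}") from e

    lda = None
    if cfg.use_lda:
        try:
            lda = feat.fit_lda(z, y)
        except ValueError as e:
            raise ValueError(f"LDA stage failed: {e}") from e
        z = feat.transform_lda(lda, z)

    svc, params, _ = train_classifier(z, y, cfg.classifier, cfg.inner_cv_folds, seed)
    return PipelineModel(config=cfg, preprocess=pm, features=fmodel, lda=lda,
                         svc=svc, chosen_params=params, rng_seed=seed,
                         outlier_flags=flags, fitted=True)
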