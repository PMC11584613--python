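"""Validation schemes, metrics with exact binomial intervals, the
principal-component sweep, and the method-comparison report.

All three schemes — leave-one-specimen-out, specimen-grouped 10-fold CV,
and repeated 80/20 holdout — split at the *specimen* level so that the
replicate measurements of one patient never straddle a train/test
boundary.  That guard is asserted on every run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import beta
from sklearn.model_selection import GroupShuffleSplit, StratifiedGroupKFold

from .classify import PipelineConfig, fit_pipeline
from .spectra_io import SpectrumSet


@dataclass
class ConfusionCounts:
    """Binary confusion counts; the positive class is cancer (label 1)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()))


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where the denominator is 0."""
    if c.n == 0:
        raise ValueError("no evaluated samples")
    acc = (c.tp + c.tn) / c.n
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return acc, sen, spec


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta quantiles.

    lower = BetaQ(alpha/2; k, n-k+1) (0 when k = 0),
    upper = BetaQ(1-alpha/2; k+1, n-k) (1 when k = n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass
class EvalResult:
    """Outcome of one validation run."""

    scheme: str
    fold_counts: list
    pooled: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    ci95: dict
    fold_accuracies: list
    config_fingerprint: str
    fold_fingerprint: str
    seed: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_folds": len(self.fold_counts),
            "pooled_counts": vars(self.pooled),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ci95": self.ci95,
            "fold_accuracies": self.fold_accuracies,
            "config_fingerprint": self.config_fingerprint,
            "fold_fingerprint": self.fold_fingerprint,
            "seed": self.seed,
            **self.extras,
        }


def _fingerprint(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _config_fingerprint(config: PipelineConfig) -> str:
    d = {k: (vars(v) if hasattr(v, "__dataclass_fields__") else v)
         for k, v in vars(config).items()}
    return _fingerprint(d)


def _assert_no_specimen_leakage(s: SpectrumSet, folds) -> None:
    """Every specimen's replicates stay on one side of every split."""
    for tr, te in folds:
        shared = set(s.specimen_ids[tr]) & set(s.specimen_ids[te])
        if shared:
            raise RuntimeError(f"specimen leakage across split: {sorted(shared)[:3]}")


def _fold_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(i,))
               .generate_state(1)[0] % (2 ** 31))


def _run_folds(s: SpectrumSet, folds, config: PipelineConfig, scheme: str,
               seed: int) -> EvalResult:
    """Refit the pipeline from scratch on every fold and pool counts."""
    _assert_no_specimen_leakage(s, folds)
    fold_counts, fold_acc = [], []
    preds = np.full(s.n_samples, -1)
    for i, (tr, te) in enumerate(folds):
        model = fit_pipeline(s.select(tr), config, seed=_fold_seed(seed, i))
        y_pred = model.predict(s.select(te))
        preds[te] = y_pred
        c = ConfusionCounts.from_predictions(s.labels[te], y_pred)
        fold_counts.append(c)
        fold_acc.append(metrics(c)[0])
    pooled = sum(fold_counts, ConfusionCounts())
    acc, sen, spec = metrics(pooled)
    ci = {
        "accuracy": clopper_pearson(pooled.tp + pooled.tn, pooled.n),
        "sensitivity": (clopper_pearson(pooled.tp, pooled.tp + pooled.fn)
                        if pooled.tp + pooled.fn > 0 else (float("nan"),) * 2),
        "specificity": (clopper_pearson(pooled.tn, pooled.tn + pooled.fp)
                        if pooled.tn + pooled.fp > 0 else (float("nan"),) * 2),
    }
    return EvalResult(
        scheme=scheme, fold_counts=fold_counts, pooled=pooled,
        accuracy=acc, sensitivity=sen, specificity=spec, ci95=ci,
        fold_accuracies=fold_acc,
        config_fingerprint=_config_fingerprint(config),
        fold_fingerprint=_fingerprint([[int(i) for i in te] for _, te in folds]),
        seed=seed,
        extras={"predictions": preds.tolist()},
    )


def leave_one_specimen_out(s: SpectrumSet, config: PipelineConfig | None = None,
                           seed: int = 0) -> EvalResult:
    """One fold per specimen: all of its replicates are the test set.

    Besides sample-level pooled metrics, a specimen-level majority-vote
    accuracy is reported (ties broken toward the positive class).
    """
    config = config if config is not None else PipelineConfig()
    specimens = pd.unique(s.specimen_ids)
    if specimens.size < 2:
        raise ValueError("leave-one-specimen-out needs >= 2 specimens")
    idx = np.arange(s.n_samples)
    folds = []
    for sp in specimens:
        te = idx[s.specimen_ids == sp]
        if te.size == 0:
            raise ValueError(f"specimen {sp!r} has no samples")
        folds.append((idx[s.specimen_ids != sp], te))
    res = _run_folds(s, folds, config, "loocv", seed)
    preds = np.asarray(res.extras["predictions"])
    votes_correct = 0
    for sp in specimens:
        mask = s.specimen_ids == sp
        vote = 1 if preds[mask].mean() >= 0.5 else 0
        truth = int(round(s.labels[mask].mean()))
        votes_correct += int(vote == truth)
    res.extras["specimen_vote_accuracy"] = votes_correct / specimens.size
    return res


def grouped_kfold(s: SpectrumSet, folds: int = 10, seed: int = 0,
                  config: PipelineConfig | None = None) -> EvalResult:
    """Specimen-grouped, label-stratified k-fold cross-validation."""
    config = config if config is not None else PipelineConfig()
    n_specimens = pd.unique(s.specimen_ids).size
    if folds > n_specimens:
        raise ValueError(f"{folds} folds but only {n_specimens} specimens")
    sgkf = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(sgkf.split(s.absorbance, s.labels, groups=s.specimen_ids))
    res = _run_folds(s, split, config, "kfold", seed)
    res.extras["mean_fold_accuracy"] = float(np.mean(res.fold_accuracies))
    return res


def make_holdout_split(s: SpectrumSet, test_fraction: float, seed: int,
                       max_retries: int = 20):
    """Specimen-level train/test split with both classes on both sides."""
    for attempt in range(max_retries):
        gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction,
                                random_state=seed + attempt)
        tr, te = next(gss.split(s.absorbance, s.labels, groups=s.specimen_ids))
        if np.unique(s.labels[tr]).size == 2 and np.unique(s.labels[te]).size == 2:
            return tr, te
    raise ValueError("could not stratify holdout split: a partition kept "
                     "missing a class after bounded retries")


def holdout(s: SpectrumSet, test_fraction: float = 0.2, repeats: int = 1,
            seed: int = 0, config: PipelineConfig | None = None) -> EvalResult:
    """Repeated specimen-level 80/20 holdout; metrics averaged over repeats."""
    config = config if config is not None else PipelineConfig()
    fold_counts, fold_acc, splits = [], [], []
    for r in range(repeats):
        tr, te = make_holdout_split(s, test_fraction, _fold_seed(seed, r))
        _assert_no_specimen_leakage(s, [(tr, te)])
        model = fit_pipeline(s.select(tr), config, seed=_fold_seed(seed, 1000 + r))
        c = ConfusionCounts.from_predictions(s.labels[te], model.predict(s.select(te)))
        fold_counts.append(c)
        fold_acc.append(metrics(c)[0])
        splits.append([int(i) for i in te])
    pooled = sum(fold_counts, ConfusionCounts())
    acc, sen, spec = metrics(pooled)
    ci = {"accuracy": clopper_pearson(pooled.tp + pooled.tn, pooled.n)}
    return EvalResult(
        scheme="holdout", fold_counts=fold_counts, pooled=pooled,
        accuracy=acc, sensitivity=sen, specificity=spec, ci95=ci,
        fold_accuracies=fold_acc,
        config_fingerprint=_config_fingerprint(config),
        fold_fingerprint=_fingerprint(splits), seed=seed,
        extras={"mean_accuracy": float(np.mean(fold_acc)),
                "sd_accuracy": float(np.std(fold_acc, ddof=1)) if repeats > 1 else 0.0},
    )


def pc_sweep(s: SpectrumSet, k_values, scheme: str = "kfold",
             config: PipelineConfig | None = None, seed: int = 0,
             **scheme_kwargs) -> pd.DataFrame:
    """Re-run a full evaluation per component count k, all else fixed.

    Returns a table of (k, accuracy, sensitivity, specificity) ordered by
    k; infeasible k values are skipped with a warning.
    """
    config = config if config is not None else PipelineConfig()
    rows = []
    for k in sorted(k_values):
        cfg = replace(config, k=int(k))
        try:
            res = run_scheme(s, scheme, cfg, seed=seed, **scheme_kwargs)
        except ValueError as e:
            warnings.warn(f"k={k} infeasible, skipped: {e}")
            continue
        rows.append({"k": int(k), "accuracy": res.accuracy,
                     "sensitivity": res.sensitivity, "specificity": res.specificity})
    return pd.DataFrame(rows, columns=["k", "accuracy", "sensitivity", "specificity"])


METHOD_CONFIGS = {
    "lda_svm": dict(feature_mode="none", use_lda=True),
    "pca_svm": dict(use_lda=False),
    "pca_lda_svm": dict(use_lda=True),
}


def comparison_report(s: SpectrumSet, methods=None, scheme: str = "kfold",
                      config: PipelineConfig | None = None, seed: int = 0,
                      **scheme_kwargs) -> pd.DataFrame:
    """Method-comparison matrix over {LDA-SVM, PCA-SVM, PCA-LDA-SVM} with
    pooled vs class-specific (dual) PCA, sharing fold assignments so the
    comparison is paired."""
    config = config if config is not None else PipelineConfig()
    if methods is None:
        methods = [("lda_svm", None), ("pca_svm", "single"), ("pca_svm", "dual"),
                   ("pca_lda_svm", "single"), ("pca_lda_svm", "dual")]
    rows = []
    for method, pca_mode in methods:
        if method not in METHOD_CONFIGS:
            raise ValueError(f"unknown method {method!r}")
        overrides = dict(METHOD_CONFIGS[method])
        if method != "lda_svm":
            overrides["feature_mode"] = "dual_pca" if pca_mode == "dual" else "single_pca"
        cfg = replace(config, **overrides)
        res = run_scheme(s, scheme, cfg, seed=seed, **scheme_kwargs)
        rows.append({
            "method": method, "pca_mode": pca_mode or "none",
            "accuracy": res.accuracy, "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "accuracy_ci_low": res.ci95["accuracy"][0],
            "accuracy_ci_high": res.ci95["accuracy"][1],
            "fold_fingerprint": res.fold_fingerprint,
        })
    return pd.DataFrame(rows)


def run_scheme(s: SpectrumSet, scheme: str, config: PipelineConfig,
               seed: int = 0, **kwargs) -> EvalResult:
    """Dispatch to one of the three validation schemes by name."""
    if scheme == "loocv":
        return leave_one_specimen_out(s, config, seed=seed)
    if scheme == "kfold":
        return grouped_kfold(s, kwargs.get("folds", 10), seed, config)
    if scheme == "holdout":
        return holdout(s, kwargs.get("test_fraction", 0.2),
                       kwargs.get("repeats", 1), seed, config)
    raise ValueError(f"unknown scheme {scheme!r}")
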