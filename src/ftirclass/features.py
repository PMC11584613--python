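"""Dimensionality reduction: pooled PCA, class-specific dual PCA with
score concatenation, and a closed-form Fisher LDA.

The dual-PCA feature map is the core of the method: one PCA is fitted on
each class of the *training* data and every sample — train or test, label
unseen — is projected into both principal spaces, yielding 2k concatenated
scores that preserve class-specific variance directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA


@dataclass
class PCAModel:
    """Fitted principal component basis.

    components rows are orthonormal loadings with the sign convention that
    each row's largest-magnitude entry is positive (reproducible across
    linear-algebra back-ends).  Covariance uses the sample (n-1)
    normalization throughout.
    """

    mean: np.ndarray
    components: np.ndarray          # (k, d), orthonormal rows
    explained_variance: np.ndarray  # (k,) eigenvalues of the sample covariance
    explained_variance_ratio: np.ndarray
    k: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.mean.size:
            raise ValueError(
                f"feature dimension {x.shape[1]} != fitted dimension {self.mean.size}")
        return (x - self.mean) @ self.components.T


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for row in out:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return out


def fit_pca(x: np.ndarray, k: int | None = None,
            variance_target: float | None = None) -> PCAModel:
    """Fit PCA on the rows of x, keeping k components.

    Exactly one of k / variance_target may be given; with variance_target
    the smallest k whose cumulative explained-variance ratio reaches the
    target is kept.  k may not exceed min(n_samples - 1, n_features), the
    rank bound of the sample covariance.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    kmax = min(n - 1, d)
    if k is not None and variance_target is not None:
        raise ValueError("give k or variance_target, not both")
    if k is not None and not 1 <= k <= kmax:
        raise ValueError(f"k={k} outside rank bound [1, {kmax}]")
    sk = _SkPCA(n_components=kmax, svd_solver="full").fit(x)
    ratios = sk.explained_variance_ratio_
    if k is None:
        k = select_k_by_variance(ratios, variance_target) if variance_target is not None else kmax
    return PCAModel(
        mean=sk.mean_,
        components=_fix_signs(sk.components_[:k]),
        explained_variance=sk.explained_variance_[:k],
        explained_variance_ratio=ratios[:k],
        k=k,
    )


def select_k_by_variance(ratios: np.ndarray, target: float) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches target.

    If the target is never reached, all components are kept and a warning
    is issued.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("empty explained-variance ratios")
    cum = np.cumsum(ratios)
    # small slack so e.g. a ratio summing to exactly the target passes
    reached = cum >= target - 1e-12
    if not reached.any():
        warnings.warn(
            f"variance target {target} not reached (max {cum[-1]:.6f}); keeping all "
            f"{ratios.size} components", stacklevel=2)
        return int(ratios.size)
    return int(np.argmax(reached)) + 1


@dataclass
class DualPCAModel:
    """Two per-class PCA models sharing a component count.

    Emits 2k concatenated scores: [scores under the class-0 basis | scores
    under the class-1 basis], applied label-blind to any sample.
    """

    pca0: PCAModel
    pca1: PCAModel

    @property
    def k(self) -> int:
        return self.pca0.k

    @property
    def out_dim(self) -> int:
        return self.pca0.k + self.pca1.k


def fit_dual_pca(x: np.ndarray, y: np.ndarray, k: int) -> DualPCAModel:
    """Fit one PCA per class on the labeled training rows, shared k."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y)
    models = {}
    for c in (0, 1):
        rows = x[y == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c} has {rows.shape[0]} training rows; needs >= 2")
        kmax = min(rows.shape[0] - 1, rows.shape[1])
        if k > kmax:
            raise ValueError(f"k={k} exceeds rank bound {kmax} for class {c}")
        models[c] = fit_pca(rows, k=k)
    return DualPCAModel(pca0=models[0], pca1=models[1])


def transform_dual(m: DualPCAModel, x: np.ndarray) -> np.ndarray:
    """Concatenated label-blind scores under both class bases."""
    return np.hstack([m.pca0.transform(x), m.pca1.transform(x)])


@dataclass
class LDAModel:
    """One-dimensional Fisher discriminant for a binary problem.

    direction is the unit-norm vector collinear with Sw^-1 (mu1 - mu0),
    oriented so class 1 projects above class 0; threshold sits at the
    midpoint of the projected class means (equal priors).
    """

    direction: np.ndarray
    threshold: float
    class_means: tuple[float, float]  # projected (class 0, class 1)


def fit_lda(z: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> LDAModel:
    """Closed-form Fisher LDA with a small ridge on the within-class scatter.

    Sw is the pooled (unnormalized) within-class scatter; the ridge
    ridge * trace(Sw)/m * I keeps it invertible when the feature count
    exceeds the class sizes, as happens with concatenated PCA scores in
    small folds.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"LDA needs exactly 2 classes, got {classes.size}")
    mus = {}
    m = z.shape[1]
    sw = np.zeros((m, m))
    for c in classes:
        rows = z[y == c]
        mus[c] = rows.mean(axis=0)
        dev = rows - mus[c]
        sw += dev.T @ dev
    tr = np.trace(sw)
    sw_reg = sw + (ridge * (tr if tr > 0 else 1.0) / m) * np.eye(m)
    delta = mus[classes[1]] - mus[classes[0]]
    direction = np.linalg.solve(sw_reg, delta)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("degenerate LDA: class means coincide")
    direction /= norm
    p0 = float(mus[classes[0]] @ direction)
    p1 = float(mus[classes[1]] @ direction)
    return LDAModel(direction=direction, threshold=(p0 + p1) / 2.0,
                    class_means=(p0, p1))


def transform_lda(m: LDAModel, z: np.ndarray) -> np.ndarray:
    """Project rows of z on the discriminant direction; (n, 1) output."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != m.direction.size:
        raise ValueError(
            f"feature dimension {z.shape[1]} != direction dimension {m.direction.size}")
    return (z @ m.direction)[:, None]
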