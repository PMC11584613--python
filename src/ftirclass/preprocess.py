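"""Spectral preprocessing: Z-score outlier flagging, asymmetric least
squares baseline correction, and train-only per-wavenumber standardization.

Every spectrum passes through the identical chain; the only *fitted* stage
is the normalizer, whose statistics come exclusively from training data so
that no test-set information leaks into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded

from .spectra_io import SpectrumSet


@dataclass
class PreprocessModel:
    """Parameters and fitted statistics of the preprocessing chain.

    alss_lambda is the second-difference smoothness penalty (unitless, >0),
    alss_p the asymmetry weight in (0,1): residuals above the baseline get
    weight p, residuals below get 1-p, so a small p pushes the baseline
    under positive peaks.
    """

    z_threshold: float = 3.0
    alss_lambda: float = 1e5
    alss_p: float = 0.01
    alss_iters: int = 10
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None
    fitted: bool = field(default=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alss_p < 1.0:
            raise ValueError(f"alss_p must be in (0, 1), got {self.alss_p}")
        if self.alss_lambda <= 0:
            raise ValueError(f"alss_lambda must be > 0, got {self.alss_lambda}")
        if self.alss_iters < 1:
            raise ValueError(f"alss_iters must be >= 1, got {self.alss_iters}")


def flag_outliers(s: SpectrumSet, z_threshold: float = 3.0) -> np.ndarray:
    """Flag samples whose total absorbance is a Z-score outlier.

    The per-sample summary is the sum of the spectrum; a sample is flagged
    when |summary - mean| / sd exceeds z_threshold (sample sd, ddof 1).
    With zero spread nothing is flagged.
    """
    if s.n_samples < 2:
        raise ValueError("outlier flagging needs at least 2 samples")
    totals = s.absorbance.sum(axis=1)
    sd = totals.std(ddof=1)
    if sd == 0:
        return np.zeros(s.n_samples, dtype=bool)
    z = np.abs(totals - totals.mean()) / sd
    return z > z_threshold


def _penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper banded storage (bandwidth 2) of lam * D2'D2 for the n-point
    second-difference operator D2."""
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    pen = (lam * (d2.T @ d2)).tocsr()
    ab = np.zeros((3, n))
    ab[2] = pen.diagonal(0)
    ab[1, 1:] = pen.diagonal(1)
    ab[0, 2:] = pen.diagonal(2)
    return ab


def alss_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                  iters: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric least squares baseline of a single spectrum.

    Finds z minimizing  sum_i w_i (y_i - z_i)^2 + lam * sum_i (d2 z_i)^2
    with the weights re-estimated each iteration: w_i = p where y_i > z_i,
    else 1 - p.  Returns (baseline, corrected) with corrected = y - z.

    Constants and straight lines are in the null space of the penalty, so
    they are reproduced exactly and the corrected spectrum is zero.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("ALSS needs a 1-D spectrum of at least 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    PreprocessModel(alss_lambda=lam, alss_p=p, alss_iters=iters)  # validate
    ab = _penalty_bands(y.size, lam)
    w = np.ones_like(y)
    z = y
    for _ in range(iters):
        sys = ab.copy()
        sys[2] += w
        z = solveh_banded(sys, w * y, lower=False)
        w = np.where(y > z, p, 1.0 - p)
    return z, y - z


def alss_correct_matrix(a: np.ndarray, lam: float, p: float, iters: int) -> np.ndarray:
    """Baseline-correct every row of an absorbance matrix."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    out = np.empty_like(a)
    for i, row in enumerate(a):
        out[i] = alss_baseline(row, lam, p, iters)[1]
    return out


def fit_normalizer(train: SpectrumSet | np.ndarray,
                   model: PreprocessModel | None = None) -> PreprocessModel:
    """Learn per-wavenumber mean and sd (ddof 1) from training spectra.

    Columns with zero spread record sd = 0 and are mapped to 0 on apply.
    """
    x = train.absorbance if isinstance(train, SpectrumSet) else np.atleast_2d(train)
    if x.shape[0] == 0:
        raise ValueError("cannot fit normalizer on an empty training set")
    m = model if model is not None else PreprocessModel()
    m.norm_mean = x.mean(axis=0)
    m.norm_sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    m.fitted = True
    return m


def apply_normalizer(m: PreprocessModel, s: SpectrumSet) -> SpectrumSet:
    """Standardize each wavenumber by the *training* statistics in m."""
    if not m.fitted:
        raise ValueError("normalizer not fitted")
    if m.norm_mean.size != s.n_points:
        raise ValueError(
            f"grid mismatch: model fitted on {m.norm_mean.size} points, data has {s.n_points}")
    sd = m.norm_sd
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, (s.absorbance - m.norm_mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return s.with_absorbance(out)
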