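"""Reading, writing and validation of wide-format spectral datasets.

A dataset is a table with one row per measured spectrum: a sample id, a
specimen id grouping replicate measurements of the same patient/specimen,
a class label (0 = non-cancer, 1 = cancer, -1 = unknown), and one
absorbance column per wavenumber on a shared uniform grid.  The default
grid spans 700-4000 cm^-1 at 1 cm^-1 spacing (3301 points).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

LABEL_UNKNOWN = -1
DEFAULT_GRID_START = 700.0
DEFAULT_GRID_STOP = 4000.0

_GRID_RTOL = 1e-6


class SpectraValidationError(ValueError):
    """A SpectrumSet or input table violates a structural invariant."""


class GridError(SpectraValidationError):
    """The wavenumber grid is not strictly increasing and uniform."""


def default_grid(start: float = DEFAULT_GRID_START, stop: float = DEFAULT_GRID_STOP,
                 step: float = 1.0) -> np.ndarray:
    """The standard acquisition grid, inclusive of both endpoints."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def check_grid(wavenumbers: np.ndarray) -> None:
    """Raise GridError naming the first offending interval if the grid is
    not strictly increasing with uniform spacing (relative tol 1e-6)."""
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise GridError("wavenumber grid must be a non-empty 1-D vector")
    if w.size == 1:
        return
    d = np.diff(w)
    if np.any(d <= 0):
        i = int(np.argmax(d <= 0))
        raise GridError(
            f"wavenumbers not strictly increasing at interval ({w[i]:g}, {w[i + 1]:g})")
    step = d[0]
    bad = np.abs(d - step) > _GRID_RTOL * max(abs(step), 1.0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise GridError(
            f"non-uniform wavenumber spacing at interval ({w[i]:g}, {w[i + 1]:g}): "
            f"step {d[i]:g} differs from {step:g}")


@dataclass
class SpectrumSet:
    """A set of spectra on a common grid plus per-sample metadata.

    Attributes
    ----------
    wavenumbers : (n_points,) float array, strictly increasing, uniform.
    absorbance : (n_samples, n_points) float array, arbitrary units.
    sample_ids : (n_samples,) unique strings.
    specimen_ids : (n_samples,) strings; replicates of one specimen share one.
    labels : (n_samples,) int array in {0, 1, -1}; -1 marks unknown.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    specimen_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.specimen_ids = np.asarray(self.specimen_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        check_grid(self.wavenumbers)
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise SpectraValidationError(
                f"absorbance has {p} columns but grid has {self.wavenumbers.size} points")
        for name, arr in (("sample_ids", self.sample_ids),
                          ("specimen_ids", self.specimen_ids),
                          ("labels", self.labels)):
            if arr.shape != (n,):
                raise SpectraValidationError(f"{name} length {arr.shape} != n_samples {n}")
        ids, counts = np.unique(self.sample_ids, return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise SpectraValidationError(f"duplicate sample id: {dup!r}")
        if any(s is None or str(s) == "" for s in self.specimen_ids):
            raise SpectraValidationError("every sample needs a non-empty specimen_id")
        bad = ~np.isin(self.labels, (0, 1, LABEL_UNKNOWN))
        if np.any(bad):
            raise SpectraValidationError(
                f"label {self.labels[bad][0]} outside encoding {{0, 1, {LABEL_UNKNOWN}}}")

    # -- convenience --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def select(self, idx) -> "SpectrumSet":
        """Row subset (fold extraction, outlier removal); preserves order of idx."""
        idx = np.asarray(idx)
        return SpectrumSet(self.wavenumbers, self.absorbance[idx],
                           self.sample_ids[idx], self.specimen_ids[idx],
                           self.labels[idx])

    def with_absorbance(self, a: np.ndarray) -> "SpectrumSet":
        """Same metadata, new absorbance matrix (e.g. after baseline correction)."""
        return SpectrumSet(self.wavenumbers, a, self.sample_ids,
                           self.specimen_ids, self.labels)


@dataclass
class DatasetManifest:
    """Column-role mapping for a wide-format spectral CSV.

    label_map maps raw cell values (as strings) to 0/1; unmapped or missing
    values load as unknown (-1).
    """

    path: str
    id_col: str = "sample_id"
    specimen_col: str = "specimen_id"
    label_col: str = "label"
    label_map: dict = field(default_factory=lambda: {"0": 0, "1": 1})

    @classmethod
    def from_file(cls, path: str | Path) -> "DatasetManifest":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        unknown = set(raw) - {"path", "id_col", "specimen_col", "label_col", "label_map"}
        if unknown:
            raise SpectraValidationError(f"unknown manifest keys: {sorted(unknown)}")
        if "label_map" in raw:
            raw["label_map"] = {str(k): int(v) for k, v in raw["label_map"].items()}
        m = cls(**raw)
        bad = set(m.label_map.values()) - {0, 1}
        if bad:
            raise SpectraValidationError(f"label_map values {sorted(bad)} outside {{0, 1}}")
        return m


def _encode_labels(raw: pd.Series, label_map: dict) -> np.ndarray:
    out = np.full(len(raw), LABEL_UNKNOWN, dtype=int)
    for i, v in enumerate(raw):
        if pd.isna(v):
            continue
        key = str(int(v)) if isinstance(v, (int, np.integer, float)) and float(v).is_integer() \
            else str(v)
        if key in label_map:
            out[i] = label_map[key]
        else:
            raise SpectraValidationError(
                f"label value {v!r} not covered by label_map and not NA")
    return out


def load_spectra(manifest: DatasetManifest | str | Path) -> SpectrumSet:
    """Load and validate a spectral CSV described by a manifest.

    A bare path is accepted and read with the default column roles.
    Row order of the file is preserved.
    """
    if not isinstance(manifest, DatasetManifest):
        manifest = DatasetManifest(path=str(manifest))
    path = Path(manifest.path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in (manifest.id_col, manifest.specimen_col, manifest.label_col):
        if col not in df.columns:
            raise SpectraValidationError(f"column {col!r} missing from {path}")
    meta_cols = {manifest.id_col, manifest.specimen_col, manifest.label_col}
    spec_cols = []
    for c in df.columns:
        if c in meta_cols:
            continue
        try:
            float(c)
        except ValueError:
            raise SpectraValidationError(
                f"non-numeric spectral column header {c!r}") from None
        spec_cols.append(c)
    if not spec_cols:
        raise SpectraValidationError("no spectral columns found")
    wavenumbers = np.array([float(c) for c in spec_cols])
    return SpectrumSet(
        wavenumbers=wavenumbers,
        absorbance=df[spec_cols].to_numpy(dtype=float).reshape(len(df), -1),
        sample_ids=df[manifest.id_col].astype(str).to_numpy(dtype=object),
        specimen_ids=df[manifest.specimen_col].astype(str).to_numpy(dtype=object),
        labels=_encode_labels(df[manifest.label_col], manifest.label_map),
    )


def save_spectra(s: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet as a wide CSV: metadata columns first, then one
    column per wavenumber.  Unknown labels are written as empty cells."""
    s.validate()
    labels = pd.array(s.labels, dtype="Int64")
    labels[np.asarray(s.labels) == LABEL_UNKNOWN] = pd.NA
    meta = pd.DataFrame({
        "sample_id": s.sample_ids,
        "specimen_id": s.specimen_ids,
        "label": labels,
    })
    spec = pd.DataFrame(s.absorbance, columns=[repr(float(w)) for w in s.wavenumbers])
    pd.concat([meta, spec], axis=1).to_csv(path, index=False)
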