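"""Synthetic two-class spectral datasets built from a seed library.

The generator emulates the structure of a biofluid FTIR cohort without
patient data: 15 surrogate "molecular group" seed spectra (sums of
Gaussian bands standing in for isolated ATR material spectra), per-class
Gaussian weight distributions whose mean/sd offsets control class
separability, additive white noise, and replicate grouping into
specimens (3 replicates per specimen by default, sharing their group
weights and differing only in noise — mirroring repeated measurements of
one patient sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import PipelineConfig, fit_pipeline
from .evaluate import ConfusionCounts, make_holdout_split, metrics
from .spectra_io import SpectrumSet, default_grid


@dataclass
class SeedLibrary:
    """Named non-negative seed spectra on a common grid."""

    names: list
    seeds: np.ndarray        # (n_groups, n_points)
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.seeds = np.atleast_2d(np.asarray(self.seeds, dtype=float))
        if len(self.names) != self.seeds.shape[0]:
            raise ValueError("one name per seed spectrum required")
        if not np.all(np.isfinite(self.seeds)):
            raise ValueError("seed spectra must be finite")
        if np.any(self.seeds < 0):
            raise ValueError("seed spectra must be non-negative")
        if np.any(np.all(self.seeds == 0, axis=1)):
            raise ValueError("seed spectra may not be identically zero")

    @property
    def n_groups(self) -> int:
        return self.seeds.shape[0]


@dataclass
class SynthesisConfig:
    """Everything that determines one synthetic dataset.

    Per sample i of class c and group j, a weight multiplier
    g_ij ~ Normal(mu_c, sd_c) is drawn independently; the spectrum is
    sum_j base_weights[j] * g_ij * seed_j plus pointwise Normal(0,
    noise_sd) noise.  noise_sd = None resolves to 1% of the peak height
    of the class-0 mean clean spectrum.
    """

    base_weights: np.ndarray | None = None
    mu0: float = 1.0
    mu1: float = 1.12
    sd0: float = 0.05
    sd1: float = 0.05
    n_per_class: int = 100
    noise_sd: float | None = None
    replicates_per_specimen: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.sd0 < 0 or self.sd1 < 0:
            raise ValueError("class sds must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates_per_specimen < 1:
            raise ValueError("replicates_per_specimen must be >= 1")
        if self.base_weights is not None:
            self.base_weights = np.asarray(self.base_weights, dtype=float)
            if not np.all(np.isfinite(self.base_weights)):
                raise ValueError("base weights must be finite")


def make_seed_library(n_groups: int = 15, bands_per_group=(3, 8), seed: int = 0,
                      wavenumbers: np.ndarray | None = None) -> SeedLibrary:
    """Surrogate seed spectra: each group is a sum of 3-8 Gaussian bands
    with centers across the grid, widths 8-60 cm^-1 and heights 0.1-1."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    lo, hi = bands_per_group
    if not 1 <= lo <= hi:
        raise ValueError("invalid bands_per_group range")
    w = default_grid() if wavenumbers is None else np.asarray(wavenumbers, dtype=float)
    rng = np.random.default_rng(seed)
    seeds = np.zeros((n_groups, w.size))
    for g in range(n_groups):
        for _ in range(rng.integers(lo, hi + 1)):
            center = rng.uniform(w[0], w[-1])
            width = rng.uniform(8.0, 60.0)
            height = rng.uniform(0.1, 1.0)
            seeds[g] += height * np.exp(-0.5 * ((w - center) / width) ** 2)
    names = [f"group{g + 1:02d}" for g in range(n_groups)]
    return SeedLibrary(names=names, seeds=seeds, wavenumbers=w)


def average_group(spectra: np.ndarray) -> np.ndarray:
    """Pointwise mean of a group of spectra on a common grid — the
    procedure that turns a group of related material spectra into one
    seed spectrum."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[0] == 0:
        raise ValueError("cannot average an empty group")
    return spectra.mean(axis=0)


def resolve_noise_sd(lib: SeedLibrary, cfg: SynthesisConfig) -> float:
    """Default noise level: 1% of the class-0 mean clean spectrum's peak."""
    if cfg.noise_sd is not None:
        return float(cfg.noise_sd)
    b = np.ones(lib.n_groups) if cfg.base_weights is None else cfg.base_weights
    clean = cfg.mu0 * (b @ lib.seeds)
    return 0.01 * float(np.max(np.abs(clean)))


def synthesize_dataset(lib: SeedLibrary, cfg: SynthesisConfig) -> SpectrumSet:
    """Draw a labeled two-class SpectrumSet from the generator model.

    Replicates of one specimen share the group weights g_ij and differ
    only in their additive noise.  Deterministic under cfg.rng_seed.
    """
    b = np.ones(lib.n_groups) if cfg.base_weights is None else cfg.base_weights
    if b.size != lib.n_groups:
        raise ValueError(f"{b.size} base weights for {lib.n_groups} groups")
    noise_sd = resolve_noise_sd(lib, cfg)
    rng = np.random.default_rng(cfg.rng_seed)
    rows, sample_ids, specimen_ids, labels = [], [], [], []
    rep = cfg.replicates_per_specimen
    for c, (mu, sd) in enumerate(((cfg.mu0, cfg.sd0), (cfg.mu1, cfg.sd1))):
        remaining = cfg.n_per_class
        spec_no = 0
        while remaining > 0:
            spec_no += 1
            n_rep = min(rep, remaining)
            remaining -= n_rep
            g = rng.normal(mu, sd, size=lib.n_groups)
            clean = (b * g) @ lib.seeds
            for r in range(n_rep):
                noise = rng.normal(0.0, noise_sd, size=lib.wavenumbers.size) \
                    if noise_sd > 0 else 0.0
                rows.append(clean + noise)
                specimen_ids.append(f"c{c}_s{spec_no:03d}")
                sample_ids.append(f"c{c}_s{spec_no:03d}_r{r + 1}")
                labels.append(c)
    return SpectrumSet(wavenumbers=lib.wavenumbers, absorbance=np.vstack(rows),
                       sample_ids=sample_ids, specimen_ids=specimen_ids,
                       labels=labels)


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=key)
               .generate_state(1)[0] % (2 ** 31))


def contour_study(lib: SeedLibrary, base_cfg: SynthesisConfig,
                  mean_diffs, sd_diffs, seed: int = 0,
                  pipeline_config: PipelineConfig | None = None,
                  test_fraction: float = 0.2) -> np.ndarray:
    """Class-separability study: test accuracy of an 80/20 specimen-split
    SVM model over a (delta-mean x delta-sd) grid of class offsets.

    Cell (i, j) synthesizes a dataset with mu1 = mu0 + mean_diffs[i] and
    sd1 = sd0 + sd_diffs[j], trains the pipeline on 80% of specimens and
    records held-out accuracy.  Deterministic under seed.
    """
    mean_diffs = np.atleast_1d(np.asarray(mean_diffs, dtype=float))
    sd_diffs = np.atleast_1d(np.asarray(sd_diffs, dtype=float))
    if mean_diffs.size == 0 or sd_diffs.size == 0:
        raise ValueError("mean_diffs and sd_diffs must be non-empty")
    pcfg = pipeline_config if pipeline_config is not None else PipelineConfig()
    acc = np.zeros((mean_diffs.size, sd_diffs.size))
    for i, dmu in enumerate(mean_diffs):
        for j, dsd in enumerate(sd_diffs):
            cell_seed = _derived_seed(seed, i, j)
            cfg = SynthesisConfig(
                base_weights=base_cfg.base_weights, mu0=base_cfg.mu0,
                mu1=base_cfg.mu0 + dmu, sd0=base_cfg.sd0,
                sd1=base_cfg.sd0 + dsd, n_per_class=base_cfg.n_per_class,
                noise_sd=base_cfg.noise_sd,
                replicates_per_specimen=base_cfg.replicates_per_specimen,
                rng_seed=cell_seed)
            s = synthesize_dataset(lib, cfg)
            tr, te = make_holdout_split(s, test_fraction, _derived_seed(seed, i, j, 1))
            model = fit_pipeline(s.select(tr), pcfg, seed=_derived_seed(seed, i, j, 2))
            counts = ConfusionCounts.from_predictions(
                s.labels[te], model.predict(s.select(te)))
            acc[i, j] = metrics(counts)[0]
    return acc
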