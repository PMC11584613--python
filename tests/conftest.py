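import numpy as np
import pytest

import ftirclass as fc


@pytest.fixture(scope="session")
def small_grid():
    """A short uniform grid (301 points, 700-1000 cm^-1) for fast runs."""
    return fc.default_grid(700, 1000)


@pytest.fixture(scope="session")
def seed_library(small_grid):
    return fc.make_seed_library(15, seed=7, wavenumbers=small_grid)


@pytest.fixture(scope="session")
def separable_set(seed_library):
    """Clearly separable two-class dataset (large class-mean offset)."""
    cfg = fc.SynthesisConfig(n_per_class=30, mu1=1.4, rng_seed=11)
    return fc.synthesize_dataset(seed_library, cfg)


@pytest.fixture
def fast_config():
    """Pipeline config with a minimal classifier grid for quick end-to-end
    tests; the scientific stages are untouched."""
    return fc.PipelineConfig(
        classifier=fc.ClassifierSpec(kernels=("linear",), C_grid=(1.0,)),
        inner_cv_folds=3,
    )


def random_spectrum_set(rng, n_samples=None, n_points=None):
    """A random valid SpectrumSet with a random uniform grid."""
    n = int(rng.integers(1, 6)) if n_samples is None else n_samples
    p = int(rng.integers(5, 21)) if n_points is None else n_points
    start = rng.uniform(400, 900)
    step = rng.uniform(0.5, 4.0)
    wav = start + step * np.arange(p)
    specimens = [f"sp{i // 2}" for i in range(n)]
    labels = rng.integers(0, 2, size=n)
    return fc.SpectrumSet(
        wavenumbers=wav,
        absorbance=rng.normal(size=(n, p)),
        sample_ids=[f"s{i}" for i in range(n)],
        specimen_ids=specimens,
        labels=labels,
    )
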