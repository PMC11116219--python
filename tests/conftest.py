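"""Shared fixtures: small phantom pools for unit tests, a larger cohort model
for the end-to-end completion benchmarks. Everything is generated in memory
from fixed seeds; no data files are required."""

from __future__ import annotations

import numpy as np
import pytest

import cranioshape as cs

SMALL_GRID = (48, 48, 48)
SMALL_SPEC = cs.PhantomSpec(grid_shape=SMALL_GRID, radii=(18.0, 15.0, 16.5), thickness=3.5)

# study conditions of the end-to-end synthetic benchmark
BENCH_COHORT_SEED = 11
BENCH_TEST_SEED = 777
BENCH_POOL_SIZE = 20
BENCH_CASES = [
    # (kind, size_fraction, lobe count, defect seed)
    ("sphere", 0.20, 1, 50),
    ("cube", 0.25, 1, 51),
    ("multi_lobe", 0.30, 2, 52),
    ("sphere", 0.15, 1, 53),
    ("border_crossing", 0.20, 1, 54),
    ("cube", 0.30, 1, 55),
    ("sphere", 0.25, 1, 56),
    ("multi_lobe", 0.20, 2, 57),
    ("cube", 0.10, 1, 58),
    ("sphere", 0.30, 1, 59),
]


@pytest.fixture(scope="session")
def small_phantom() -> cs.BinaryVolume:
    return cs.generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_cohort() -> list[cs.BinaryVolume]:
    return cs.generate_cohort(8, base_spec=SMALL_SPEC, seed=5)


@pytest.fixture(scope="session")
def small_pool(small_cohort) -> cs.ShapePool:
    return cs.build_pool(small_cohort,
                         reference_index=cs.choose_reference(small_cohort))


@pytest.fixture(scope="session")
def small_model(small_pool) -> cs.ShapeModel:
    return cs.fit_variations(small_pool)


@pytest.fixture(scope="session")
def bench_cohort() -> list[cs.BinaryVolume]:
    return cs.generate_cohort(BENCH_POOL_SIZE, seed=BENCH_COHORT_SEED)


@pytest.fixture(scope="session")
def bench_model(bench_cohort) -> cs.ShapeModel:
    pool = cs.build_pool(bench_cohort,
                         reference_index=cs.choose_reference(bench_cohort))
    return cs.fit_variations(pool)


@pytest.fixture(scope="session")
def bench_test_phantoms() -> list[cs.BinaryVolume]:
    return cs.generate_cohort(12, seed=BENCH_TEST_SEED)[:10]


def random_blob_volume(rng: np.random.Generator, shape=(32, 32, 32),
                       n_seeds: int = 3, dilations: int = 3) -> cs.BinaryVolume:
    """A random connected-ish blobby mask for metric/extraction tests."""
    from scipy import ndimage

    data = np.zeros(shape, dtype=bool)
    idx = rng.integers(4, np.asarray(shape) - 4, size=(n_seeds, 3))
    data[tuple(idx.T)] = True
    data = ndimage.binary_dilation(data, iterations=dilations)
    return cs.BinaryVolume(data.astype(np.uint8))
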