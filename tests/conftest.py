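"""Shared fixtures: seeded RNGs, patch factories and a small shared cohort."""

from __future__ import annotations

import numpy as np
import pytest

from ustex.simulate import (
    Cohort,
    SyntheticCohortConfig,
    generate_cohort,
)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng) -> np.ndarray:
    return rng.integers(0, 256, (64, 64), dtype=np.int64)


@pytest.fixture
def constant_patch() -> np.ndarray:
    return np.full((64, 64), 100, dtype=np.int64)


@pytest.fixture(scope="session")
def tiny_cohort() -> Cohort:
    """A small shared cohort (12 patients, 2 iterations) for structural
    checks that do not depend on cohort size."""
    cfg = SyntheticCohortConfig(
        n_f0=5, n_f4=7, frames_mean=4, frames_sd=1.5, frames_min=2, frames_max=6
    )
    return generate_cohort(cfg, rng=np.random.default_rng(999), iterations=2)
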