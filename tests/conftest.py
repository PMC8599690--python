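"""Shared fixtures: small lattices and cohorts generated at test time."""

import numpy as np
import pytest

from fearsig import (
    CVScheme,
    CohortConfig,
    default_ground_truth,
    default_space,
    generate_cohort,
)


@pytest.fixture(scope="session")
def tiny_space():
    """~500-voxel lattice, 30 parcels, full network taxonomy."""
    return default_space(dims=(12, 12, 10))


@pytest.fixture(scope="session")
def tiny_truth(tiny_space):
    return default_ground_truth(tiny_space, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_space, tiny_truth):
    """8 subjects x 30 trials on the tiny lattice (trial set, condition set,
    events)."""
    cfg = CohortConfig(
        n_subjects=8, trials_per_subject=30, drop_top_level_subjects=0, seed=3
    )
    return generate_cohort(tiny_space, tiny_truth, cfg)


@pytest.fixture(scope="session")
def tiny_scheme():
    return CVScheme(n_folds=4, n_repeats=2, seed=0)


@pytest.fixture(scope="session")
def noiseless_truth(tiny_space):
    return default_ground_truth(
        tiny_space, seed=7, sigma_within=0.0, sigma_between=0.0,
        suppressor_sd=0.0,
    )
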