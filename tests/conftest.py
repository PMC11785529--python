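import dataclasses

import numpy as np
import pytest

from nppeval.grid import GridSpec
from nppeval.synthetic import default_truth, simulate_truth_dataset


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec.regular(n_lat=8, n_lon=10, n_years=26)


@pytest.fixture(scope="session")
def noise_free_truth(small_grid):
    return default_truth(small_grid, seed=3, n_models=5, noise_sd=0.0, ar1_phi=0.0)


@pytest.fixture(scope="session")
def noise_free_dataset(small_grid, noise_free_truth):
    ds, _ = simulate_truth_dataset(small_grid, noise_free_truth)
    return ds


@pytest.fixture(scope="session")
def noisy_dataset(small_grid):
    truth = default_truth(small_grid, seed=9, n_models=5, noise_sd=0.03, ar1_phi=0.3)
    ds, _ = simulate_truth_dataset(small_grid, truth)
    return ds, truth


@pytest.fixture
def shifted_truth(noise_free_truth):
    """Five-member ensemble whose per-driver shifts increase in magnitude."""
    shifts = np.array(
        [
            [0.05, 0.04, 0.03],
            [0.10, 0.08, 0.06],
            [0.15, 0.12, 0.09],
            [0.20, 0.16, 0.12],
            [0.25, 0.20, 0.15],
        ]
    )
    return dataclasses.replace(
        noise_free_truth,
        ensemble_shifts=shifts,
        ensemble_delta_npp=np.array([-0.5, -1.0, -1.5, -2.0, -2.5]),
    )
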