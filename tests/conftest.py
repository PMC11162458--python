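import numpy as np
import pytest

from tempodyn.basis import make_fast_basis, make_slow_basis
from tempodyn.fitting import average_trials, fit_dn, preprocess
from tempodyn.models import predict_dn
from tempodyn.stimulus import VSDI_GRID, make_condition_set
from tempodyn.synthetic import GeneratorSpec, default_dn_truth, generate_dataset


@pytest.fixture(scope="session")
def grid():
    return VSDI_GRID


@pytest.fixture(scope="session")
def fast_basis(grid):
    return make_fast_basis(grid)


@pytest.fixture(scope="session")
def slow_basis(grid):
    return make_slow_basis(grid)


@pytest.fixture(scope="session")
def conditions():
    return make_condition_set()


@pytest.fixture(scope="session")
def dn_truth(grid, fast_basis):
    return default_dn_truth(grid, fast_basis)


@pytest.fixture(scope="session")
def truth_fast_components(conditions, dn_truth, fast_basis):
    """Noiseless evoked component per condition under the canonical truth."""
    return {
        c.condition_id: predict_dn(c, dn_truth, fast_basis).fast for c in conditions
    }


@pytest.fixture(scope="session")
def noisy_dataset(grid, fast_basis, dn_truth, truth_fast_components):
    """The reference noisy recovery dataset: 10% noise, 8 repeats, seed 0."""
    peak = max(v.max() for v in truth_fast_components.values())
    spec = GeneratorSpec(grid, "dn", dn_truth, fast_basis, noise_sd=0.1 * peak, seed=0)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def noisy_avg(noisy_dataset):
    trials, blanks, _ = noisy_dataset
    return average_trials(preprocess(trials, blanks))


@pytest.fixture(scope="session")
def dn_fit(noisy_avg, conditions, fast_basis, slow_basis):
    """DN fit to the reference dataset, shared across the suite."""
    return fit_dn(noisy_avg, conditions, fast_basis, slow_basis, seed=0, n_restarts=5)
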