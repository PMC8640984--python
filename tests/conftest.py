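"""Shared fixtures: small synthetic datasets and fitted gold standards.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive objects to one construction per run.
"""

import numpy as np
import pytest

from sparsebench import _cd
from sparsebench.gold import fit_gold_standard
from sparsebench.preprocessing import preprocess
from sparsebench.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the coordinate-descent kernels once up front so individual
    test timings reflect the algorithms, not JIT latency."""
    rng = np.random.default_rng(0)
    x = np.asfortranarray(rng.standard_normal((20, 5)))
    y = rng.standard_normal(20)
    _cd.solve_l0_path(x, y, np.geomspace(1.0, 0.1, 3), 0.01, 0.01, 1e-6, 50, 10)
    _cd.solve_l0(x, y, np.zeros(5), 0.1, 0.0, 0.0, 1e-6, 50, 10)
    _cd.objective(x, y, np.zeros(5), 0.1, 0.0, 0.0)


@pytest.fixture(scope="session")
def small_dataset():
    """One high-SNR synthetic dataset, raw (n=300, 40 variables)."""
    config = SyntheticConfig(
        n_samples=300, n_variables=40, snr_regime="high", seed=11
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def small_prepped(small_dataset):
    dataset, truth = small_dataset
    prepped, report = preprocess(dataset)
    return prepped, truth, report


@pytest.fixture(scope="session")
def small_gold(small_prepped):
    """Gold standard on the small dataset: response vs the other columns."""
    prepped, truth, _ = small_prepped
    resp = prepped.variable_ids.index(truth.response_id)
    pred_idx = [j for j in range(prepped.n_variables) if j != resp]
    x = prepped.values[:, pred_idx]
    y = prepped.values[:, resp]
    gs = fit_gold_standard(
        x, y, variable_ids=[prepped.variable_ids[j] for j in pred_idx]
    )
    return gs, x, y
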