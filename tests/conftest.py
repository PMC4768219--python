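import numpy as np
import pandas as pd
import pytest

from tfcrosstalk.expression import ExpressionMatrix
from tfcrosstalk.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One moderate simulated study shared by read-only tests."""
    return simulate_study(SimulationConfig(n_genes=300, rng_seed=11))


@pytest.fixture(scope="session")
def noisefree_study():
    """Zero-noise study: every downstream call is forced by construction."""
    return simulate_study(SimulationConfig(n_genes=300, noise_sd=0.0, rng_seed=5))


@pytest.fixture()
def tiny_matrix():
    """Two genes, two conditions, hand-checkable numbers."""
    values = pd.DataFrame(
        {
            "Ctr_1": [3.0, 5.0],
            "Ctr_2": [3.0, 5.2],
            "TNF_1": [4.0, 5.3],
            "TNF_2": [4.2, 4.9],
        },
        index=["gA", "gB"],
    )
    cmap = {"Ctr_1": "Ctr", "Ctr_2": "Ctr", "TNF_1": "TNF", "TNF_2": "TNF"}
    return ExpressionMatrix(values, cmap)


def make_null_matrix(n_genes, n_rep=3, noise_sd=0.25, seed=0, conditions=("Ctr", "TNF")):
    """Pure-noise matrix: all genes null across the given conditions."""
    rng = np.random.default_rng(seed)
    cols = {}
    cmap = {}
    base = rng.normal(8.0, 1.0, size=n_genes)
    for cond in conditions:
        for r in range(1, n_rep + 1):
            name = f"{cond}_{r}"
            cols[name] = base + rng.normal(0.0, noise_sd, size=n_genes)
            cmap[name] = cond
    values = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return ExpressionMatrix(values, cmap)
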