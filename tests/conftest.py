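import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hyposcreen.dataset import ExpressionDataset
from hyposcreen.simulate import (
    SimExpressionConfig,
    default_subtype_catalog,
    make_toy_fixture,
    simulate_expression,
)


@pytest.fixture(scope="session")
def toy():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def catalog():
    return default_subtype_catalog()


@pytest.fixture(scope="session")
def small_sim():
    """600-cell, 1,000-gene dataset at default study conditions, no QC
    violators (shared across read-only tests)."""
    cfg = SimExpressionConfig(
        n_cells_per_group={"Y": 200, "O": 200, "O.T": 200},
        n_genes=1000,
        qc_violator_fraction=0.0,
        seed=11,
    )
    return simulate_expression(cfg)


def manual_dataset(counts, groups=None, cell_types=None, mito=None):
    """Small helper to build a dataset from an explicit count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "group": groups if groups is not None else ["Y"] * n,
            "cell_type": cell_types if cell_types is not None else ["Neuron"] * n,
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )
    mito = mito if mito is not None else [False] * g
    var = pd.DataFrame(
        {"is_mito": mito, "is_tf": [False] * g},
        index=pd.Index([f"g{j}" for j in range(g)], name="symbol"),
    )
    return ExpressionDataset(sp.csr_matrix(counts), obs, var)
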