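"""Shared fixtures: small handcrafted matrices and seeded simulations."""

import numpy as np
import pytest
import scipy.sparse as sp

from scannotate.io import CountMatrix, Clustering, log_normalize
from scannotate.simulate import (
    SimParams,
    marker_catalog,
    simulate_coexpression,
    simulate_hierarchy,
    simulate_two_group,
)


@pytest.fixture(scope="session")
def toy_counts() -> CountMatrix:
    """3 genes x 4 cells with exact hand-checkable counts."""
    counts = np.array(
        [
            [10, 0, 3, 1],
            [0, 5, 0, 2],
            [2, 2, 2, 2],
        ]
    )
    return CountMatrix(["Actb", "Cd19", "Gapdh"], ["c1", "c2", "c3", "c4"], sp.csr_matrix(counts))


@pytest.fixture(scope="session")
def two_group():
    """Small two-group simulation with DE ground truth."""
    p = SimParams(n_genes=300, n_cells=400, de_prob=0.1, seed=21).with_mean_depth(2000.0)
    m, meta, truth = simulate_two_group(p)
    return m, meta, truth


@pytest.fixture(scope="session")
def homogeneous():
    """Signal-free matrix (de_prob=0) with arbitrary two-group labels —
    the correct null for calibration checks."""
    p = SimParams(n_genes=400, n_cells=600, de_prob=0.0, seed=7).with_mean_depth(2000.0)
    m, meta, _ = simulate_two_group(p)
    m = log_normalize(m)
    c = Clustering(resolution=0.0, labels=meta["group"].to_numpy())
    return m, c


@pytest.fixture(scope="session")
def hierarchy_flat():
    """4 well-separated cell types with 25 exclusive markers each."""
    p = SimParams(n_genes=400, n_cells=600, seed=7).with_mean_depth(2000.0)
    m, meta = simulate_hierarchy(4, nesting=0, p=p)
    m = log_normalize(m)
    c = Clustering(resolution=0.0, labels=meta["curated_label"].to_numpy())
    catalog = marker_catalog(meta, m)
    return m, meta, c, catalog


@pytest.fixture(scope="session")
def hierarchy_nested():
    """4 types x 2 graded subtypes — the resolution-selection fixture."""
    p = SimParams(n_genes=400, n_cells=600, seed=7).with_mean_depth(2000.0)
    m, meta = simulate_hierarchy(4, nesting=1, p=p)
    m = log_normalize(m)
    return m, meta


@pytest.fixture(scope="session")
def coexpression():
    """Planted 3-module coexpression data for gene-program discovery."""
    m, modules, states = simulate_coexpression(seed=5)
    m = log_normalize(m)
    c = Clustering(resolution=0.0, labels=states)
    return m, modules, c
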