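"""Shared fixtures: toy count matrices and small simulated datasets."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
import scipy.sparse as sp

from ambiquant import CountMatrix, SimulationParams, simulate_dataset


def make_counts(array, barcodes=None, gene_ids=None, gene_symbols=None) -> CountMatrix:
    """CountMatrix from a dense array with auto-generated identifiers."""
    array = np.asarray(array)
    n_bc, n_genes = array.shape
    if barcodes is None:
        barcodes = [f"BC{i}" for i in range(n_bc)]
    if gene_ids is None:
        gene_ids = [f"G{j}" for j in range(n_genes)]
    return CountMatrix(sp.csr_matrix(array), np.array(barcodes, dtype=object),
                       np.array(gene_ids, dtype=object),
                       None if gene_symbols is None else np.array(gene_symbols, dtype=object))


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """Scaled-down dataset sizes for fast unit tests."""
    return SimulationParams(
        n_cells_center=150,
        n_droplets_center=900,
        biological_umi_center=600,
        ambient_umi_level=30.0,
        n_clusters=3,
        n_genes=400,
        randomize=False,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_params)


@pytest.fixture(scope="session")
def zero_ambient_dataset(small_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_params.replace(ambient_umi_level=0.0))


@pytest.fixture(scope="session")
def high_ambient_dataset(small_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_params.replace(ambient_umi_level=500.0))
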