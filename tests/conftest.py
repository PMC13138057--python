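"""Shared fixtures: one synthetic study (bulk + cells) reused across tests."""

import numpy as np
import pytest

import scidentity as sid


@pytest.fixture(scope="session")
def bulk_truth():
    return sid.generate_bulk(seed=1)


@pytest.fixture(scope="session")
def salient(bulk_truth):
    bulk, _ = bulk_truth
    return sid.select_salient_genes(bulk)


@pytest.fixture(scope="session")
def model(bulk_truth, salient):
    bulk, truth = bulk_truth
    sub = bulk.subset_genes(salient.genes)
    return sid.fit_identity_model(sub, k_grid=range(2, 9), seed=1)


@pytest.fixture(scope="session")
def factor_map(bulk_truth, salient, model):
    """Model factor name -> planted identity name (Hungarian matching on W)."""
    from scipy.optimize import linear_sum_assignment

    bulk, truth = bulk_truth
    idx = [truth.gene_ids.index(g) for g in salient.genes]
    C = np.corrcoef(model.W.T, truth.W_true[idx].T)[: model.k, model.k:]
    rows, cols = linear_sum_assignment(-C)
    return {model.factor_names[i]: truth.identity_names[j] for i, j in zip(rows, cols)}


@pytest.fixture(scope="session")
def cells_labels(bulk_truth):
    _, truth = bulk_truth
    return sid.generate_single_cells(truth, seed=1)


@pytest.fixture(scope="session")
def profiles(cells_labels, model):
    cells, _ = cells_labels
    return sid.map_cells(cells, model)
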