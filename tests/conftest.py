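import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import crossvasc as cv


def make_dataset(counts, species="At", cell_prefix="c", gene_prefix="g", normalized=None):
    """Small dense-counts helper for hand fixtures."""
    counts = np.asarray(counts)
    ds = cv.ExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=[f"{cell_prefix}{i}" for i in range(counts.shape[0])],
        gene_ids=[f"{gene_prefix}{j}" for j in range(counts.shape[1])],
        species=species,
    )
    if normalized is not None:
        ds.normalized = sp.csr_matrix(np.asarray(normalized, dtype=float))
    return ds


@pytest.fixture(scope="session")
def small_sim():
    """Two-species simulation at reduced size, shared across tests."""
    cfg = cv.SimulationConfig(n_cells_per_species=200, n_genes=300, seed=3)
    ds_a, ds_b, truth = cv.simulate_two_species(cfg)
    return cfg, ds_a, ds_b, truth


@pytest.fixture(scope="session")
def small_forest():
    return cv.simulate_gene_forest(
        n_trees=60, species_codes=["At", "Pt", "Os", "Zm"], max_leaves=12, dup_prob=0.3, seed=7
    )


def true_time_series(dataset, truth):
    return pd.Series(
        [truth.true_time[c] for c in dataset.cell_ids], index=pd.Index(dataset.cell_ids)
    )


def translate_b_to_a(dataset_b, truth):
    """Rename species-B genes into A's ID space via the true ortholog pairs."""
    pair_map = dict(truth.ortho_pairs)
    table = cv.ExtendedHomologTable(
        table=pd.DataFrame(
            [(g, pair_map.get(g, g)) for g in dataset_b.gene_ids],
            columns=["source_gene", "translated_id"],
        )
    )
    return cv.apply_homolog_table(dataset_b, table)
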