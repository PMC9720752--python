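"""Shared data model for cross-species single-cell trajectory comparison.

The central container is :class:`ExpressionDataset`, a cells × genes sparse
count matrix with string identifiers, a species tag, per-cell metadata and an
optional normalized layer.  It is deliberately lighter than ``AnnData``: the
pipeline only ever needs counts, one normalized layer and a metadata table,
and a small container keeps the invariants explicit and checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class CrossvascError(Exception):
    """Base class for errors raised by this package."""


class FormatError(CrossvascError):
    """An external file violates the expected format."""


class ContractError(CrossvascError):
    """An operation was called on inputs violating its preconditions."""


def _as_csr(matrix) -> sp.csr_matrix:
    m = sp.csr_matrix(matrix)
    m.sum_duplicates()
    return m


@dataclass
class ExpressionDataset:
    """Cells × genes expression matrix for one species.

    Parameters
    ----------
    counts
        Sparse matrix of non-negative integer UMI counts, cells in rows.
    cell_ids, gene_ids
        Unique, case-sensitive identifier strings for the two axes.
    species
        Short species code, e.g. ``"Pt"`` or ``"At"``.
    cell_meta
        Per-cell metadata table indexed by ``cell_ids`` (cluster labels,
        pseudotime, QC statistics accumulate here as the pipeline runs).
    normalized
        Optional log-normalized layer with the same shape and axis order as
        ``counts``; present only after normalization.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    species: str
    cell_meta: pd.DataFrame = None  # type: ignore[assignment]
    normalized: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ContractError(
                f"axis lengths ({len(self.cell_ids)} cells, {len(self.gene_ids)} genes) "
                f"do not match counts shape {self.counts.shape}"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ContractError("duplicate cell_ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ContractError("duplicate gene_ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ContractError("negative counts")
            if not np.issubdtype(data.dtype, np.integer):
                if np.any(data != np.round(data)):
                    raise ContractError("non-integer counts")
        if list(self.cell_meta.index) != self.cell_ids:
            raise ContractError("cell_meta rows do not correspond one-to-one with cell_ids")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ContractError("normalized layer shape differs from counts")

    # ------------------------------------------------------------------
    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 for each cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def total_counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ContractError(f"genes not in dataset: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, keep: Iterable[str]) -> "ExpressionDataset":
        keep = list(keep)
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in keep], dtype=int)
        return ExpressionDataset(
            counts=self.counts[idx],
            cell_ids=keep,
            gene_ids=list(self.gene_ids),
            species=self.species,
            cell_meta=self.cell_meta.iloc[idx].copy(),
            normalized=None if self.normalized is None else _as_csr(self.normalized)[idx],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(genes)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=list(genes),
            species=self.species,
            cell_meta=self.cell_meta.copy(),
            normalized=None if self.normalized is None else _as_csr(self.normalized)[:, idx],
        )

    def rename_genes(self, mapping: dict[str, str]) -> "ExpressionDataset":
        new_ids = [mapping.get(g, g) for g in self.gene_ids]
        dup = pd.Series(new_ids).value_counts()
        dup = dup[dup > 1]
        if len(dup):
            raise ContractError(f"renaming produces duplicate gene ids: {sorted(dup.index)[:10]}")
        return ExpressionDataset(
            counts=self.counts.copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=new_ids,
            species=self.species,
            cell_meta=self.cell_meta.copy(),
            normalized=None if self.normalized is None else self.normalized.copy(),
        )

    def normalized_dense(self) -> np.ndarray:
        if self.normalized is None:
            raise ContractError("normalized layer missing; run normalize_lognorm first")
        return np.asarray(self.normalized.todense())

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            counts=self.counts.copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            species=self.species,
            cell_meta=self.cell_meta.copy(),
            normalized=None if self.normalized is None else self.normalized.copy(),
        )


@dataclass
class GroundTruth:
    """Simulation truth used for recovery testing.

    gene_class maps every simulated gene id (in either species' namespace)
    to ``conserved`` / ``divergent`` / ``flat``; ortho_pairs are the true
    one-to-one cross-species pairs (paralog-duplicated genes are excluded
    from them and recorded in paralog_groups instead).
    """

    gene_class: dict[str, str]
    true_time: dict[str, float]
    true_cluster: dict[str, int]
    ortho_pairs: list[tuple[str, str]]
    paralog_groups: dict[str, list[str]] = field(default_factory=dict)
    # auxiliary simulation internals for moment/profile checks
    log_baseline: dict[str, float] = field(default_factory=dict)
    library_size: dict[str, float] = field(default_factory=dict)
    profile_grid: np.ndarray | None = None
    profiles: dict[str, np.ndarray] = field(default_factory=dict)
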