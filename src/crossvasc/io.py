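"""Readers and writers for the pipeline's external formats.

Count matrices use the 10x Genomics triplet convention: a MatrixMarket
coordinate file oriented genes × cells plus one-column ``features.tsv`` and
``barcodes.tsv`` files.  Internally everything is cells × genes.  Gene
forests are newick, one rooted tree per line, with leaf labels of the form
``SPECIES|geneID``.  Homolog tables are two-column TSVs with a header row.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import log
from .datamodel import ExpressionDataset, FormatError
from .orthomap import GeneTree, TreeNode

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
HOMOLOG_COLUMNS = ("Populus", "Arabidopsis")


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_count_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    species: str,
) -> ExpressionDataset:
    """Read a 10x-style MTX triplet into a cells × genes dataset.

    The MTX file is genes × cells (features × barcodes); the returned counts
    are transposed to cells × genes. Coordinates absent from the file are 0.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    genes = _read_id_column(Path(features_path))
    cells = _read_id_column(Path(barcodes_path))
    if mat.shape[0] != len(genes) or mat.shape[1] != len(cells):
        raise FormatError(
            f"matrix header says {mat.shape[0]} genes x {mat.shape[1]} cells but "
            f"features/barcodes files list {len(genes)} / {len(cells)}"
        )
    if mat.data.size and not np.issubdtype(mat.data.dtype, np.integer):
        if np.any(mat.data != np.round(mat.data)):
            raise FormatError(f"non-integer count values in {matrix_path}")
        mat = mat.astype(np.int64)
    dataset = ExpressionDataset(
        counts=mat.T.tocsr(),
        cell_ids=cells,
        gene_ids=genes,
        species=species,
    )
    log.info(
        "read_count_matrix: %s -> %d cells x %d genes (species %s)",
        matrix_path, dataset.n_cells, dataset.n_genes, species,
    )
    return dataset


def write_count_matrix(dataset: ExpressionDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the 10x triplet (genes × cells MTX + features + barcodes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / MATRIX_FILE,
        "features": out / FEATURES_FILE,
        "barcodes": out / BARCODES_FILE,
    }
    mat = sp.coo_matrix(dataset.counts.T).astype(np.int64)
    scipy.io.mmwrite(str(paths["matrix"]), mat, field="integer")
    paths["features"].write_text("".join(g + "\n" for g in dataset.gene_ids))
    paths["barcodes"].write_text("".join(c + "\n" for c in dataset.cell_ids))
    return paths


# ----------------------------------------------------------------------
# Gene forests
# ----------------------------------------------------------------------

def _convert_dendropy(node: dendropy.Node) -> TreeNode:
    if node.is_leaf():
        label = node.taxon.label if node.taxon is not None else (node.label or "")
        if "|" not in label:
            raise FormatError(f"leaf label {label!r} lacks the 'SPECIES|geneID' separator")
        species, gene_id = label.split("|", 1)
        return TreeNode(gene_id=gene_id, species=species)
    return TreeNode(children=[_convert_dendropy(c) for c in node.child_nodes()])


def read_gene_forest(newick_path: str | Path) -> list[GeneTree]:
    """Read one rooted newick tree per line; leaves labeled SPECIES|geneID."""
    trees: list[GeneTree] = []
    with open(newick_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                dtree = dendropy.Tree.get(
                    data=line, schema="newick", preserve_underscores=True
                )
            except Exception as exc:
                raise FormatError(f"{newick_path}:{lineno}: unparsable newick: {exc}") from exc
            root = _convert_dendropy(dtree.seed_node)
            # a root with a single child wrapping one leaf collapses to the leaf
            while len(root.children) == 1:
                root = root.children[0]
            trees.append(GeneTree(root=root, tree_id=f"tree{lineno}"))
    log.info("read_gene_forest: %s -> %d trees", newick_path, len(trees))
    return trees


def write_gene_forest(trees: list[GeneTree], newick_path: str | Path) -> None:
    Path(newick_path).write_text("".join(t.to_newick() + "\n" for t in trees))


# ----------------------------------------------------------------------
# Homolog tables and generic TSV
# ----------------------------------------------------------------------

def read_homolog_table(tsv_path: str | Path) -> pd.DataFrame:
    """Two-column (source, target) homolog TSV with a header row."""
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if table.shape[1] != 2:
        raise FormatError(
            f"{tsv_path}: expected 2 columns, found {table.shape[1]} ({list(table.columns)})"
        )
    return table


def write_homolog_table(table: pd.DataFrame, tsv_path: str | Path) -> None:
    if table.shape[1] != 2:
        raise FormatError("homolog table must have exactly two columns")
    table.to_csv(tsv_path, sep="\t", index=False)


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)
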