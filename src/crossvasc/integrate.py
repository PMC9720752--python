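"""Cross-species integration on the one-to-one ortholog feature space.

Species B's genes are translated into species A's ID space through the
one-to-one ortholog map, both matrices are restricted to the shared feature
list (orthologs plus any curated markers present in both), z-scored per
feature within species, embedded by a joint PCA, and species B is shifted
onto species A by a mutual-nearest-neighbors (MNN) correction: MNN pairs
across species define difference vectors in PC space, and each B cell is
moved by a Gaussian-kernel-weighted average of those vectors.  The corrected
embedding is then clustered jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .config import IntegrationParams, log
from .datamodel import ContractError, ExpressionDataset
from .orthomap import ExtendedHomologTable, OneToOneMap, apply_homolog_table
from .preprocess import cluster_graph, pca_embed_matrix


@dataclass
class FeatureSpace:
    """Ordered shared feature IDs with provenance (ortholog / curated)."""

    feature_ids: list[str]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ContractError("duplicate feature ids")


@dataclass
class JointEmbedding:
    """Corrected joint embedding: one row per cell of either species."""

    coords: np.ndarray
    cell_ids: list[str]
    species: np.ndarray

    def __post_init__(self) -> None:
        if self.coords.shape[0] != len(self.cell_ids) or self.coords.shape[0] != len(self.species):
            raise ContractError("embedding row count does not match cell annotations")
        if not np.all(np.isfinite(self.coords)):
            raise ContractError("non-finite embedding coordinates")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.coords, columns=[f"dim{i + 1}" for i in range(self.coords.shape[1])]
        )
        frame.insert(0, "species", self.species)
        frame.insert(0, "cell_id", self.cell_ids)
        return frame


def build_feature_space(
    one2one: OneToOneMap,
    curated: list[str],
    dataset_a: ExpressionDataset,
    dataset_b: ExpressionDataset,
) -> tuple[FeatureSpace, ExpressionDataset, ExpressionDataset]:
    """Translate B's genes to A's ID space and subset both datasets to the
    shared ortholog features (plus curated markers present in both).

    One-to-one pairs are (gene in species_a, gene in species_b) where
    species_b is the reference ID space of dataset A.  Features absent from
    either dataset are dropped with a warning.
    """
    b_to_a = {a_gene: b_gene for a_gene, b_gene in one2one.pairs}
    # rename species-B genes that have a one-to-one partner
    relevant = {g: b_to_a[g] for g in dataset_b.gene_ids if g in b_to_a}
    table = ExtendedHomologTable(
        table=pd.DataFrame(
            [(g, relevant.get(g, g)) for g in dataset_b.gene_ids],
            columns=["source_gene", "translated_id"],
        )
    )
    translated_b = apply_homolog_table(dataset_b, table)

    genes_a = set(dataset_a.gene_ids)
    genes_b = set(translated_b.gene_ids)
    features: list[str] = []
    provenance: dict[str, str] = {}
    for _, target in one2one.pairs:
        if target in genes_a and target in genes_b:
            features.append(target)
            provenance[target] = "ortholog"
    n_dropped = len(one2one.pairs) - len(features)
    if n_dropped:
        warnings.warn(f"{n_dropped} ortholog features absent from a dataset; dropped", stacklevel=2)
    for marker in curated:
        if marker in provenance:
            continue
        if marker in genes_a and marker in genes_b:
            features.append(marker)
            provenance[marker] = "curated"
        else:
            warnings.warn(f"curated marker {marker!r} absent from a dataset; dropped", stacklevel=2)
    if not features:
        raise ContractError("empty shared feature space")
    space = FeatureSpace(feature_ids=features, provenance=provenance)
    log.info(
        "build_feature_space: %d features (%d ortholog, %d curated)",
        len(features),
        sum(v == "ortholog" for v in provenance.values()),
        sum(v == "curated" for v in provenance.values()),
    )
    return space, dataset_a.subset_genes(features), translated_b.subset_genes(features)


def _zscore_within(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    return x / np.clip(x.std(axis=0), 1e-8, None)


def integrate_mnn(
    dataset_a: ExpressionDataset,
    dataset_b: ExpressionDataset,
    k: int = 15,
    n_dims: int = 30,
    smooth_sigma: float | None = None,
) -> JointEmbedding:
    """MNN-corrected joint PC embedding; species B is shifted onto A.

    Expression matrices are never altered; the correction acts only on the
    embedding.  The per-cell correction is the Gaussian-kernel weighted
    average (bandwidth ``smooth_sigma``, default the median MNN pair
    distance) of the MNN pair difference vectors.
    """
    if dataset_a.gene_ids != dataset_b.gene_ids:
        raise ContractError("datasets must share an identical ordered feature space")
    if dataset_a.n_cells < k or dataset_b.n_cells < k:
        raise ContractError(f"both datasets need at least k={k} cells")

    xa = _zscore_within(dataset_a.normalized_dense())
    xb = _zscore_within(dataset_b.normalized_dense())
    joint = pca_embed_matrix(np.vstack([xa, xb]), n_dims)
    pa, pb = joint[: dataset_a.n_cells], joint[dataset_a.n_cells:]

    nn_ab = NearestNeighbors(n_neighbors=k).fit(pb)
    _, ab = nn_ab.kneighbors(pa)  # for each A cell: its k NNs in B
    nn_ba = NearestNeighbors(n_neighbors=k).fit(pa)
    _, ba = nn_ba.kneighbors(pb)

    a_neighbors = [set(row) for row in ab]
    pairs = [
        (int(j_a), i_b)
        for i_b, row in enumerate(ba)
        for j_a in row
        if i_b in a_neighbors[int(j_a)]
    ]
    if not pairs:
        warnings.warn("no mutual nearest neighbors found; no correction applied", stacklevel=2)
        corrected_b = pb
    else:
        a_idx = np.array([p[0] for p in pairs])
        b_idx = np.array([p[1] for p in pairs])
        vectors = pa[a_idx] - pb[b_idx]
        pair_d = np.linalg.norm(vectors, axis=1)

        # per anchored B cell: Gaussian average of its own pair vectors with a
        # softmin bandwidth (the closest pair dominates), so an already-aligned
        # cell receives no spurious neighborhood-mean shift
        raw: dict[int, np.ndarray] = {}
        for i in np.unique(b_idx):
            sel = b_idx == i
            d = pair_d[sel]
            s = max(float(d.min()), 1e-8)
            w = np.exp(-(d**2) / (2.0 * s * s))
            raw[int(i)] = (w[:, None] * vectors[sel]).sum(axis=0) / w.sum()
        anchor_ids = np.array(sorted(raw))
        anchor_pos = pb[anchor_ids]
        anchor_vec = np.array([raw[i] for i in anchor_ids])

        # smooth the anchored corrections over all B cells
        d2 = cdist(pb, anchor_pos, metric="sqeuclidean")
        if smooth_sigma is None:
            smooth_sigma = max(float(np.median(np.sqrt(np.min(d2, axis=1)))), 1e-6)
        w = np.exp(-d2 / (2.0 * smooth_sigma**2))
        w[np.arange(len(pb))[:, None] == anchor_ids[None, :]] = 1.0
        w_sum = w.sum(axis=1, keepdims=True)
        far = w_sum.ravel() <= 1e-12
        corr = w @ anchor_vec / np.clip(w_sum, 1e-12, None)
        if far.any():
            corr[far] = anchor_vec.mean(axis=0)
        corrected_b = pb + corr
    embedding = JointEmbedding(
        coords=np.vstack([pa, corrected_b]),
        cell_ids=list(dataset_a.cell_ids) + list(dataset_b.cell_ids),
        species=np.array(
            [dataset_a.species] * dataset_a.n_cells + [dataset_b.species] * dataset_b.n_cells
        ),
    )
    frac = same_species_neighbor_fraction(embedding, k=k)
    log.info(
        "integrate_mnn: %d MNN pairs, sigma=%s, same-species neighbor fraction %.3f",
        len(pairs), f"{smooth_sigma:.3g}" if smooth_sigma else "n/a", frac,
    )
    return embedding


def same_species_neighbor_fraction(embedding: JointEmbedding, k: int = 15) -> float:
    """Mean fraction of same-species cells among each cell's k nearest
    neighbors (self excluded); 0.5 means perfect mixing at equal sizes."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.coords)
    _, idx = nn.kneighbors(embedding.coords)
    same = embedding.species[idx[:, 1:]] == embedding.species[:, None]
    return float(same.mean())


def joint_cluster(
    embedding: JointEmbedding, params=None, seed: int = 0
) -> pd.Series:
    """Leiden clustering of the corrected joint embedding; labels cover all
    cells of both species (delegates to the per-species clustering)."""
    from .config import ClusterParams

    params = params or ClusterParams()
    labels = cluster_graph(
        embedding.coords,
        k_neighbors=params.k_neighbors,
        resolution=params.resolution,
        seed=seed,
    )
    return pd.Series(labels, index=pd.Index(embedding.cell_ids, name="cell_id"), name="cluster")
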