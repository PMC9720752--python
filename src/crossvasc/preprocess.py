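"""Per-species QC, normalization, embedding, clustering and marker testing.

Conventions follow the droplet single-cell tooling family: nuclei are kept
by detected-gene bounds, expression is log-normalized to a fixed scale per
cell, highly variable genes are chosen by mean-binned standardized variance,
clustering is Leiden community detection on a shared-nearest-neighbor graph
in PC space, and cluster markers come from a two-sided Wilcoxon rank-sum
test with natural-log fold-change, detection-fraction and BH-adjusted
p-value thresholds.
"""

from __future__ import annotations

import itertools
import math
import warnings

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .config import ClusterParams, MarkerTestParams, QCParams, log
from .datamodel import ContractError, ExpressionDataset

LOGFC_EPS = 1e-9


# ----------------------------------------------------------------------
# QC and normalization
# ----------------------------------------------------------------------

def qc_filter(
    dataset: ExpressionDataset, params: QCParams | None = None
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Keep cells whose detected-gene count lies in [min, max] (inclusive).

    Returns the filtered dataset and a report table listing removed cells
    with their detected-gene counts and the reason for removal.
    """
    params = params or QCParams()
    detected = dataset.detected_genes_per_cell()
    low = detected < params.min_genes_per_cell
    high = detected > params.max_genes_per_cell
    keep = ~(low | high)
    if not keep.any():
        raise ContractError("QC filter removed every cell")
    reasons = np.where(low, "too_few_genes", np.where(high, "too_many_genes", ""))
    report = pd.DataFrame(
        {
            "cell_id": np.array(dataset.cell_ids)[~keep],
            "detected_genes": detected[~keep],
            "reason": reasons[~keep],
        }
    )
    kept_ids = [c for c, k in zip(dataset.cell_ids, keep) if k]
    out = dataset.subset_cells(kept_ids)
    out.cell_meta["detected_genes"] = detected[keep]
    log.info(
        "qc_filter: kept %d/%d cells (bounds [%d, %d]); removed %d low, %d high",
        out.n_cells, dataset.n_cells, params.min_genes_per_cell,
        params.max_genes_per_cell, int(low.sum()), int(high.sum()),
    )
    return out, report


def normalize_lognorm(dataset: ExpressionDataset, scale: float = 1.0e4) -> ExpressionDataset:
    """normalized[i, g] = ln(1 + counts[i, g] * scale / total_counts[i])."""
    totals = dataset.total_counts_per_cell()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ContractError(
            f"cells with zero total counts cannot be normalized: {[dataset.cell_ids[i] for i in zero[:5]]}"
        )
    out = dataset.copy()
    norm = out.counts.astype(float).multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.normalized = norm
    return out


# ----------------------------------------------------------------------
# HVG selection and PCA
# ----------------------------------------------------------------------

def select_hvg(
    dataset: ExpressionDataset, n_top: int = 2000, n_mean_bins: int = 20
) -> list[str]:
    """Top genes by standardized variance of log-normalized expression.

    Per-gene variance is z-scored against genes of similar mean (equal-count
    mean bins), removing the mean-variance trend; zero-variance genes rank
    last; ties break by gene ID.
    """
    if n_top > dataset.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds the {dataset.n_genes} genes available; clamping",
            stacklevel=2,
        )
        n_top = dataset.n_genes
    x = dataset.normalized_dense()
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])

    n_bins = min(n_mean_bins, max(1, dataset.n_genes // 2))
    order = np.argsort(mean, kind="stable")
    z = np.empty(dataset.n_genes)
    for chunk in np.array_split(order, n_bins):
        v = var[chunk]
        sd = v.std()
        z[chunk] = (v - v.mean()) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf

    ranked = sorted(zip(-z, dataset.gene_ids), key=lambda t: (t[0], t[1]))
    return [g for _, g in ranked[:n_top]]


def embed_pca(
    dataset: ExpressionDataset,
    n_pcs: int = 30,
    genes: list[str] | None = None,
) -> np.ndarray:
    """PCA of the centered, unit-scaled normalized matrix (optionally over a
    gene subset).  Component signs are fixed by making each loading vector's
    largest-magnitude entry positive, so the embedding is reproducible.
    """
    ds = dataset if genes is None else dataset.subset_genes(genes)
    x = ds.normalized_dense()
    return pca_embed_matrix(x, n_pcs)


def pca_embed_matrix(x: np.ndarray, n_pcs: int) -> np.ndarray:
    """Deterministic sign-fixed PCA of an already-assembled dense matrix."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    x = x / np.clip(sd, 1e-8, None)
    n_pcs = min(n_pcs, min(x.shape) - 1) if min(x.shape) > 1 else 1
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return u[:, :n_pcs] * s[:n_pcs]


# ----------------------------------------------------------------------
# Graph clustering
# ----------------------------------------------------------------------

def cluster_graph(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Leiden clustering of the SNN graph built from Euclidean k-NN.

    Edge weights are Jaccard overlaps of (self-inclusive) neighbor sets;
    weights below 1/15 are pruned.  Labels are relabeled by decreasing
    cluster size (largest cluster is 0).
    """
    n = embedding.shape[0]
    if n < k_neighbors + 1:
        raise ContractError(f"need at least k_neighbors+1={k_neighbors + 1} cells, got {n}")
    # canonical cell order (lexicographic by coordinates) makes the partition
    # invariant to input row order
    canon = np.lexsort(np.asarray(embedding).T[::-1])
    embedding = np.asarray(embedding)[canon]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neighbor_sets = [set(row) for row in idx]

    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w >= 1.0 / 15.0:
                edges.append((i, j))
                weights.append(w)

    g = igraph.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    g.simplify(combine_edges="max")
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=5,
    )
    raw = np.empty(n, dtype=int)
    raw[canon] = np.array(part.membership)
    return relabel_by_size(raw)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel integer labels so cluster 0 is largest; ties by old label."""
    ids, counts = np.unique(labels, return_counts=True)
    order = sorted(zip(-counts, ids))
    mapping = {old: new for new, (_, old) in enumerate(order)}
    return np.array([mapping[l] for l in labels])


def _labels_array(dataset: ExpressionDataset, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.reindex(dataset.cell_ids).to_numpy()
    labels = np.asarray(labels)
    if labels.shape[0] != dataset.n_cells:
        raise ContractError("labels length does not match number of cells")
    return labels


# ----------------------------------------------------------------------
# Wilcoxon rank-sum machinery
# ----------------------------------------------------------------------

def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact (permutation) Wilcoxon rank-sum p-value.

    Enumerates all C(n+m, n) assignments of the pooled midranks, so ties are
    handled exactly; two-sided p is twice the smaller one-sided tail, capped
    at 1.  Intended for small groups (n, m <= 8).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    t_obs = ranks[:n].sum()
    total = math.comb(len(pooled), n)
    ge = le = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        t = ranks[list(combo)].sum()
        if t >= t_obs - 1e-12:
            ge += 1
        if t <= t_obs + 1e-12:
            le += 1
    return min(1.0, 2.0 * min(ge, le) / total)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration when both groups
    have <= 8 observations, else the tie-corrected normal approximation
    (with continuity correction)."""
    if len(x) <= 8 and len(y) <= 8:
        return exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def log_fold_change(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Natural-log fold change of expm1-backtransformed normalized means."""
    return float(
        np.log(np.expm1(x_in).mean() + LOGFC_EPS) - np.log(np.expm1(x_out).mean() + LOGFC_EPS)
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    if len(pvals) == 0:
        return np.array([])
    return multipletests(pvals, method="fdr_bh")[1]


def _de_one_contrast(
    dataset: ExpressionDataset,
    in_mask: np.ndarray,
    out_mask: np.ndarray,
    params: MarkerTestParams,
    directional: bool = True,
) -> pd.DataFrame:
    """Shared Wilcoxon DE machinery for one in-vs-out contrast.

    Genes failing the detection-fraction or log-fold-change filter are
    excluded before testing (this restricts the BH universe; the counts are
    logged for auditability).
    """
    norm = dataset.normalized_dense()
    raw = dataset.counts
    x_in, x_out = norm[in_mask], norm[out_mask]
    frac_in = np.asarray((raw[in_mask] > 0).mean(axis=0)).ravel()
    frac_out = np.asarray((raw[out_mask] > 0).mean(axis=0)).ravel()

    rows = []
    for gi, gene in enumerate(dataset.gene_ids):
        lfc = log_fold_change(x_in[:, gi], x_out[:, gi])
        if directional:
            passes = lfc >= params.min_logfc and frac_in[gi] >= params.min_fraction
        else:
            passes = abs(lfc) >= params.min_logfc and (
                (lfc > 0 and frac_in[gi] >= params.min_fraction)
                or (lfc < 0 and frac_out[gi] >= params.min_fraction)
            )
        if not passes:
            continue
        rows.append(
            {
                "gene": gene,
                "logfc": lfc,
                "fraction_in": frac_in[gi],
                "fraction_out": frac_out[gi],
                "p_value": rank_sum_test(x_in[:, gi], x_out[:, gi]),
            }
        )
    result = pd.DataFrame(rows, columns=["gene", "logfc", "fraction_in", "fraction_out", "p_value"])
    result["adj_p"] = bh_adjust(result["p_value"].to_numpy())
    return result


def find_markers(
    dataset: ExpressionDataset,
    labels,
    params: MarkerTestParams | None = None,
) -> pd.DataFrame:
    """Cluster markers by two-sided Wilcoxon rank-sum, one cluster vs rest.

    Retained rows satisfy all three thresholds: natural-log fold change,
    in-cluster detection fraction, and BH-adjusted p (adjusted within each
    cluster across its tested genes).
    """
    params = params or MarkerTestParams()
    labels = _labels_array(dataset, labels)
    frames = []
    for cluster in sorted(set(labels)):
        in_mask = labels == cluster
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {cluster} has fewer than 3 cells; skipped", stacklevel=2)
            continue
        res = _de_one_contrast(dataset, in_mask, ~in_mask, params, directional=True)
        res.insert(1, "cluster", cluster)
        res = res[res["adj_p"] <= params.max_adj_p]
        frames.append(res)
        log.info("find_markers: cluster %s -> %d markers", cluster, len(res))
    if not frames:
        return pd.DataFrame(
            columns=["gene", "cluster", "logfc", "fraction_in", "fraction_out", "p_value", "adj_p"]
        )
    return pd.concat(frames, ignore_index=True)


def cluster_de(
    dataset: ExpressionDataset,
    labels,
    group_a: set,
    group_b: set,
    max_fdr: float = 0.05,
    params: MarkerTestParams | None = None,
    directional: bool = True,
) -> pd.DataFrame:
    """DEGs between two disjoint cluster groups (default: induced in
    group_a), retained at BH-adjusted p <= max_fdr."""
    params = params or MarkerTestParams()
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ContractError(f"cluster groups overlap: {sorted(group_a & group_b)}")
    labels = _labels_array(dataset, labels)
    a_mask = np.isin(labels, list(group_a))
    b_mask = np.isin(labels, list(group_b))
    if not a_mask.any() or not b_mask.any():
        raise ContractError("one of the cluster groups matches no cells")
    res = _de_one_contrast(dataset, a_mask, b_mask, params, directional=directional)
    res["direction"] = np.where(res["logfc"] >= 0, "up", "down")
    res = res[res["adj_p"] <= max_fdr].reset_index(drop=True)
    log.info(
        "cluster_de: %s vs %s -> %d DEGs at FDR<=%g",
        sorted(group_a), sorted(group_b), len(res), max_fdr,
    )
    return res


def dotplot_stats(dataset: ExpressionDataset, labels, gene_panel: list[str]) -> pd.DataFrame:
    """Per (gene, cluster): detection fraction and mean normalized expression."""
    labels = _labels_array(dataset, labels)
    idx = dataset.gene_index(gene_panel)
    norm = dataset.normalized_dense()[:, idx]
    raw = dataset.counts[:, idx]
    rows = []
    for cluster in sorted(set(labels)):
        mask = labels == cluster
        frac = np.asarray((raw[mask] > 0).mean(axis=0)).ravel()
        mean = norm[mask].mean(axis=0)
        for g, f, m in zip(gene_panel, frac, mean):
            rows.append({"gene": g, "cluster": cluster, "fraction_expressing": f, "mean_normalized": m})
    return pd.DataFrame(rows)
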