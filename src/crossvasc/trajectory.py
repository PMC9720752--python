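"""Cluster-level lineage inference and per-cell pseudotime.

A minimum spanning tree over cluster centroids in the embedding defines the
cluster-level topology; a lineage is the ordered path from a supplied start
cluster (chosen on biological grounds, e.g. the procambium-like cluster) to
a leaf.  Pseudotime is each cell's arc-length coordinate after orthogonal
projection onto the piecewise-linear curve through the lineage's ordered
centroids, optionally refined by project–reorder–refit iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .config import log
from .datamodel import ContractError, ExpressionDataset


@dataclass
class LineageSpec:
    """Ordered cluster ids of one lineage; the first element is the start."""

    clusters: tuple[int, ...]

    def __post_init__(self) -> None:
        self.clusters = tuple(int(c) for c in self.clusters)
        if len(self.clusters) < 2:
            raise ContractError("a lineage needs at least 2 clusters")
        if len(set(self.clusters)) != len(self.clusters):
            raise ContractError("lineage clusters must be distinct")

    @property
    def start(self) -> int:
        return self.clusters[0]

    def name(self) -> str:
        return "-".join(str(c) for c in self.clusters)


@dataclass
class PseudotimeAssignment:
    """Per-cell arc-length position along one lineage curve (>= 0, 0 at the
    start-cluster end)."""

    values: pd.Series  # index cell_id -> pseudotime
    lineage: LineageSpec

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ContractError("non-finite pseudotime values")
        if np.any(self.values.to_numpy() < 0):
            raise ContractError("negative pseudotime")


def _centroids(coords: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    return {
        int(c): coords[labels == c].mean(axis=0)
        for c in np.unique(labels)
    }


def fit_cluster_mst(coords: np.ndarray, labels: np.ndarray) -> nx.Graph:
    """Minimum spanning tree over cluster centroids (Euclidean weights).

    Kruskal's algorithm on edges sorted by (weight, cluster-id pair), so
    equal-weight ties resolve to the lexicographically smaller pair.
    """
    cents = _centroids(coords, np.asarray(labels))
    ids = sorted(cents)
    tree = nx.Graph()
    for c in ids:
        tree.add_node(c, centroid=cents[c])
    if len(ids) == 1:
        return tree
    edges = sorted(
        (float(np.linalg.norm(cents[a] - cents[b])), a, b)
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
    )
    parent = {c: c for c in ids}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.add_edge(a, b, weight=w)
    return tree


def extract_lineages(mst: nx.Graph, start_cluster: int) -> list[LineageSpec]:
    """One lineage per leaf reachable from the start cluster, each the
    ordered path start -> leaf; lineages sorted by terminal cluster id."""
    if start_cluster not in mst:
        raise ContractError(f"start cluster {start_cluster} not in the tree")
    leaves = sorted(
        n for n in mst.nodes if n != start_cluster and mst.degree(n) == 1
    )
    lineages = []
    for leaf in leaves:
        path = nx.shortest_path(mst, start_cluster, leaf)
        lineages.append(LineageSpec(clusters=tuple(path)))
    return lineages


def _project_onto_polyline(
    points: np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """Arc-length coordinate of each point's nearest (clamped orthogonal)
    projection onto the polyline; ties between segments go to the earlier
    segment."""
    seg_start = vertices[:-1]
    seg_vec = vertices[1:] - seg_start
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_dist = np.full(points.shape[0], np.inf)
    best_arc = np.zeros(points.shape[0])
    for s in range(seg_vec.shape[0]):
        v = seg_vec[s]
        L2 = seg_len[s] ** 2
        t = ((points - seg_start[s]) @ v) / L2 if L2 > 0 else np.zeros(points.shape[0])
        t = np.clip(t, 0.0, 1.0)
        proj = seg_start[s] + t[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_dist - 1e-12  # strict: ties stay with the earlier segment
        best_dist[better] = d[better]
        best_arc[better] = cum[s] + t[better] * seg_len[s]
    return best_arc


def compute_pseudotime(
    coords: np.ndarray,
    labels: np.ndarray,
    cell_ids: list[str],
    lineage: LineageSpec,
    refine_iters: int = 0,
) -> PseudotimeAssignment:
    """Arc-length pseudotime along the piecewise-linear centroid curve.

    Cells whose label is not in the lineage are excluded.  With
    ``refine_iters`` > 0, the curve is refined by principal-curve style
    iterations: project cells, re-estimate vertices as means of equal-count
    arc-length blocks, and refit.
    """
    labels = np.asarray(labels)
    mask = np.isin(labels, lineage.clusters)
    if not mask.any():
        raise ContractError("no cells belong to the lineage clusters")
    points = coords[mask]
    ids = [c for c, m in zip(cell_ids, mask) if m]
    cents = _centroids(coords, labels)
    vertices = np.array([cents[c] for c in lineage.clusters])
    arc = _project_onto_polyline(points, vertices)

    for _ in range(refine_iters):
        order = np.argsort(arc, kind="stable")
        blocks = np.array_split(order, max(len(lineage.clusters) * 2, 4))
        new_vertices = np.array([points[b].mean(axis=0) for b in blocks if len(b)])
        # keep orientation anchored at the start-cluster end
        start_c = cents[lineage.start]
        if np.linalg.norm(new_vertices[0] - start_c) > np.linalg.norm(new_vertices[-1] - start_c):
            new_vertices = new_vertices[::-1]
        vertices = new_vertices
        arc = _project_onto_polyline(points, vertices)

    values = pd.Series(arc, index=pd.Index(ids, name="cell_id"), name="pseudotime")
    log.info(
        "compute_pseudotime: lineage %s, %d cells, arc length %.3f",
        lineage.name(), len(ids), float(values.max()),
    )
    return PseudotimeAssignment(values=values, lineage=lineage)


def subset_lineage_cells(
    dataset: ExpressionDataset, labels, lineage: LineageSpec
) -> ExpressionDataset:
    """Cells whose cluster label belongs to the lineage, layers carried over."""
    if isinstance(labels, pd.Series):
        labels = labels.reindex(dataset.cell_ids).to_numpy()
    labels = np.asarray(labels)
    keep = [c for c, l in zip(dataset.cell_ids, labels) if int(l) in lineage.clusters]
    if not keep:
        raise ContractError("no cells in the lineage clusters")
    return dataset.subset_cells(keep)
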