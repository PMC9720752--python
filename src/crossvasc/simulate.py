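"""Synthetic two-species expression data and gene-tree forests with truth.

The expression simulator places cells of two species on a shared latent
differentiation axis t in [0, 1] and draws negative-binomial UMI counts with
log-mean  log L_i + beta0_g + b_{g,s} + f_{g,s}(t_i),  where L_i is a
lognormal library size, beta0_g a gene baseline, b_{g,s} a per-gene species
offset (batch effect) and f_{g,s} a smooth profile.  Conserved genes share
one profile across species; divergent genes get independently drawn,
verified-dissimilar profiles; flat genes have f = 0.  A configurable
fraction of species-B genes is emitted as two paralog copies of one
species-A gene.  The forest simulator grows rooted gene trees where each
internal node is, by construction, a duplication (children inherit the
species set) or a speciation (children partition it), recording the true
event labels, parsed groups and one-to-one pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SimulationConfig, log
from .datamodel import ContractError, ExpressionDataset, GroundTruth
from .orthomap import DUPLICATION, SPECIATION, GeneTree, TreeNode

SPECIES_A = "At"
SPECIES_B = "Pt"

_PROFILE_GRID = np.linspace(0.0, 1.0, 101)


def largest_remainder_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Integer class sizes summing to n by the largest-remainder rule.

    Ties in fractional part break toward the earlier class.
    """
    raw = [n * p for p in proportions]
    base = [math.floor(x) for x in raw]
    remainder = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return base


def sample_nb(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean mu, dispersion theta) with Var = mu + mu^2/theta.

    theta = inf degenerates to Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    if np.isinf(theta):
        return rng.poisson(mu)
    return rng.negative_binomial(theta, theta / (theta + mu))


# ----------------------------------------------------------------------
# Expression profiles
# ----------------------------------------------------------------------

def _draw_profile(rng: np.random.Generator, amplitude_range: tuple[float, float]) -> np.ndarray:
    """One smooth profile f: [0,1] -> R, evaluated on the shared grid."""
    a = rng.uniform(*amplitude_range) * rng.choice([-1.0, 1.0])
    family = rng.integers(0, 3)
    t = _PROFILE_GRID
    if family == 0:  # linear
        f = a * (t - 0.5)
    elif family == 1:  # logistic front
        k = rng.uniform(6.0, 14.0)
        m = rng.uniform(0.3, 0.7)
        f = a * (1.0 / (1.0 + np.exp(-k * (t - m))) - 0.5)
    else:  # unimodal peak
        m = rng.uniform(0.2, 0.8)
        w = rng.uniform(0.1, 0.2)
        f = a * (np.exp(-((t - m) ** 2) / (2 * w * w)) - 0.5)
    return f


def _profile_corr(f: np.ndarray, g: np.ndarray) -> float:
    if np.std(f) == 0 or np.std(g) == 0:
        return 0.0
    return float(np.corrcoef(f, g)[0, 1])


def _interp(f_grid: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.interp(t, _PROFILE_GRID, f_grid)


# ----------------------------------------------------------------------
# Two-species expression simulation
# ----------------------------------------------------------------------

def simulate_two_species(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, GroundTruth]:
    """Generate species A ("At"-like reference) and species B ("Pt"-like)
    datasets with ground truth; deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    n_cells = config.n_cells_per_species

    n_cons, n_div, n_flat = largest_remainder_counts(n_genes, config.class_proportions)
    classes = ["conserved"] * n_cons + ["divergent"] * n_div + ["flat"] * n_flat

    a_ids = [f"AT{i:04d}" for i in range(n_genes)]
    b_base_ids = [f"PT{i:04d}" for i in range(n_genes)]

    # profiles per base gene and species, on the shared grid
    profiles_a = np.zeros((n_genes, _PROFILE_GRID.size))
    profiles_b = np.zeros((n_genes, _PROFILE_GRID.size))
    for i, cls in enumerate(classes):
        if cls == "conserved":
            f = _draw_profile(rng, config.amplitude_range)
            profiles_a[i] = f
            profiles_b[i] = f
        elif cls == "divergent":
            f = _draw_profile(rng, config.amplitude_range)
            # redraw the partner until the patterns are genuinely dissimilar,
            # so "divergent" is an unambiguous class label
            for _ in range(200):
                g = _draw_profile(rng, config.amplitude_range)
                if _profile_corr(f, g) < 0.3:
                    break
            profiles_a[i] = f
            profiles_b[i] = g

    beta0 = rng.normal(np.log(1.0 / n_genes), config.baseline_log_sd, size=n_genes)
    batch_a = rng.normal(0.0, config.batch_sd, size=n_genes) if config.batch_sd > 0 else np.zeros(n_genes)
    batch_b = rng.normal(0.0, config.batch_sd, size=n_genes) if config.batch_sd > 0 else np.zeros(n_genes)

    # paralog duplications in species B
    n_paralog = int(round(config.paralog_fraction * n_genes))
    paralog_idx = set(map(int, rng.choice(n_genes, size=n_paralog, replace=False))) if n_paralog else set()

    b_gene_ids: list[str] = []
    b_source_idx: list[int] = []
    paralog_groups: dict[str, list[str]] = {}
    for i in range(n_genes):
        if i in paralog_idx:
            copies = [f"{b_base_ids[i]}a", f"{b_base_ids[i]}b"]
            paralog_groups[a_ids[i]] = copies
            b_gene_ids.extend(copies)
            b_source_idx.extend([i, i])
        else:
            b_gene_ids.append(b_base_ids[i])
            b_source_idx.append(i)
    b_source_idx_arr = np.array(b_source_idx)

    ortho_pairs = [
        (b_base_ids[i], a_ids[i]) for i in range(n_genes) if i not in paralog_idx
    ]

    truth = GroundTruth(
        gene_class={},
        true_time={},
        true_cluster={},
        ortho_pairs=ortho_pairs,
        paralog_groups=paralog_groups,
        profile_grid=_PROFILE_GRID.copy(),
        profiles={SPECIES_A: profiles_a, SPECIES_B: profiles_b},
    )
    for i, cls in enumerate(classes):
        truth.gene_class[a_ids[i]] = cls
    for j, i in enumerate(b_source_idx):
        truth.gene_class[b_gene_ids[j]] = classes[i]

    def one_species(
        species: str,
        gene_ids: list[str],
        prof: np.ndarray,
        source_idx: np.ndarray,
        batch: np.ndarray,
    ) -> ExpressionDataset:
        t = rng.uniform(0.0, 1.0, size=n_cells)
        lib = rng.lognormal(np.log(config.mean_library_size), config.library_size_log_sd, size=n_cells)
        cluster = np.minimum(
            (t * config.n_clusters_per_lineage).astype(int),
            config.n_clusters_per_lineage - 1,
        )
        f_cells = np.empty((n_cells, len(gene_ids)))
        for j, i in enumerate(source_idx):
            f_cells[:, j] = _interp(prof[i], t)
        log_mu = (
            np.log(lib)[:, None]
            + beta0[source_idx][None, :]
            + batch[source_idx][None, :]
            + f_cells
        )
        counts = sample_nb(rng, np.exp(log_mu), config.nb_dispersion)
        cell_ids = [f"{species}_c{i:04d}" for i in range(n_cells)]
        meta = pd.DataFrame(
            {"true_time": t, "true_cluster": cluster, "library_size": lib},
            index=pd.Index(cell_ids, name="cell_id"),
        )
        for cid, ti, ci, li in zip(cell_ids, t, cluster, lib):
            truth.true_time[cid] = float(ti)
            truth.true_cluster[cid] = int(ci)
            truth.library_size[cid] = float(li)
        for j, g in enumerate(gene_ids):
            truth.log_baseline[g] = float(beta0[source_idx[j]] + batch[source_idx[j]])
        return ExpressionDataset(
            counts=sp.csr_matrix(counts),
            cell_ids=cell_ids,
            gene_ids=list(gene_ids),
            species=species,
            cell_meta=meta,
        )

    ds_a = one_species(SPECIES_A, a_ids, profiles_a, np.arange(n_genes), batch_a)
    ds_b = one_species(SPECIES_B, b_gene_ids, profiles_b, b_source_idx_arr, batch_b)
    log.info(
        "simulate_two_species: %d+%d cells, %d A-genes, %d B-genes (%d paralog pairs), classes %d/%d/%d",
        n_cells, n_cells, len(a_ids), len(b_gene_ids), n_paralog, n_cons, n_div, n_flat,
    )
    return ds_a, ds_b, truth


# ----------------------------------------------------------------------
# Gene-forest simulation
# ----------------------------------------------------------------------

@dataclass
class ForestTruth:
    """Simulated forest with per-node truth.

    events[i] maps each internal node of tree i — identified by the
    frozenset of its subtree's leaf gene ids — to its true event label.
    groups[i] is the list of true parsed ortho-groups of tree i as
    (gene_id, species) lists.
    """

    trees: list[GeneTree]
    events: list[dict[frozenset, str]] = field(default_factory=list)
    groups: list[list[list[tuple[str, str]]]] = field(default_factory=list)

    def true_one_to_one(self, species_a: str, species_b: str) -> list[tuple[str, str]]:
        pairs = []
        for tree_groups in self.groups:
            for grp in tree_groups:
                a = sorted(g for g, s in grp if s == species_a)
                b = sorted(g for g, s in grp if s == species_b)
                if len(a) == 1 and len(b) == 1:
                    pairs.append((a[0], b[0]))
        return sorted(pairs)


def simulate_gene_forest(
    n_trees: int,
    species_codes: list[str],
    max_leaves: int = 12,
    dup_prob: float = 0.3,
    seed: int = 0,
) -> ForestTruth:
    """Grow ``n_trees`` rooted gene trees with known duplication/speciation
    events.

    Each internal node is a duplication (both children inherit the full
    species set) with probability ``dup_prob`` whenever the leaf budget
    permits, otherwise a speciation (children partition the species set), so
    every species assigned to a subtree is realized in it and the
    species-overlap criterion recovers the true labels exactly.
    """
    if max_leaves < 2:
        raise ContractError("max_leaves must be >= 2")
    if len(species_codes) < 2:
        raise ContractError("need at least 2 species codes")
    rng = np.random.default_rng(seed)
    truth = ForestTruth(trees=[])

    for tree_idx in range(n_trees):
        counter = [0]
        events: dict[frozenset, str] = {}

        def leaf(species: str) -> TreeNode:
            gid = f"t{tree_idx:03d}n{counter[0]:03d}"
            counter[0] += 1
            return TreeNode(gene_id=gid, species=species)

        def build(species: tuple[str, ...], budget: int) -> TreeNode:
            assert budget >= len(species)
            if len(species) == 1:
                if budget >= 2 and rng.random() < dup_prob:
                    b1 = int(rng.integers(1, budget))
                    node = TreeNode(children=[build(species, b1), build(species, budget - b1)])
                    events[frozenset(l.gene_id for l in node.leaves())] = DUPLICATION
                    return node
                return leaf(species[0])
            if budget >= 2 * len(species) and rng.random() < dup_prob:
                b1 = int(rng.integers(len(species), budget - len(species) + 1))
                node = TreeNode(children=[build(species, b1), build(species, budget - b1)])
                events[frozenset(l.gene_id for l in node.leaves())] = DUPLICATION
            else:
                k1 = int(rng.integers(1, len(species)))
                perm = list(rng.permutation(len(species)))
                s1 = tuple(sorted(species[i] for i in perm[:k1]))
                s2 = tuple(sorted(species[i] for i in perm[k1:]))
                b1 = int(rng.integers(len(s1), budget - len(s2) + 1))
                node = TreeNode(children=[build(s1, b1), build(s2, budget - b1)])
                events[frozenset(l.gene_id for l in node.leaves())] = SPECIATION
            return node

        n_target = int(rng.integers(2, max_leaves + 1))
        n_species = int(rng.integers(1, min(len(species_codes), n_target) + 1))
        root_species = tuple(
            sorted(rng.choice(species_codes, size=n_species, replace=False))
        )
        root = build(root_species, n_target)
        tree = GeneTree(root=root, tree_id=f"sim{tree_idx:03d}")
        truth.trees.append(tree)
        truth.events.append(events)

        # true parsed groups, derived from the recorded events alone
        groups: list[list[tuple[str, str]]] = []

        def subtree_dup_free(node: TreeNode) -> bool:
            for n in node.postorder():
                if not n.is_leaf:
                    key = frozenset(l.gene_id for l in n.leaves())
                    if events[key] == DUPLICATION:
                        return False
            return True

        def descend(node: TreeNode) -> None:
            if subtree_dup_free(node):
                groups.append([(l.gene_id, l.species) for l in node.leaves()])
                return
            for c in node.children:
                descend(c)

        descend(root)
        truth.groups.append(groups)

    return truth
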