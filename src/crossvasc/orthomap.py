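"""Ortholog mapping from reconciled gene trees.

Gene trees over many species are parsed into duplication-free ortho-groups:
each internal node is labeled a duplication when at least two of its child
subtrees share a species (the species-overlap criterion), else a speciation.
Cutting the tree at every duplication node yields maximal duplication-free
subtrees; a group containing exactly one gene from each of two focal species
contributes a one-to-one ortholog pair.  Many-to-one homology tables are
disambiguated with dot-number suffixes so that paralogs sharing a single
target-species homolog remain distinguishable after gene-ID translation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .config import log
from .datamodel import ContractError, ExpressionDataset

SPECIATION = "speciation"
DUPLICATION = "duplication"


class TreeNode:
    """Node of a rooted gene tree; leaves carry (gene_id, species)."""

    __slots__ = ("children", "gene_id", "species", "event")

    def __init__(self, children=None, gene_id=None, species=None):
        self.children: list[TreeNode] = children or []
        self.gene_id: str | None = gene_id
        self.species: str | None = species
        self.event: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def species_set(self) -> frozenset[str]:
        return frozenset(l.species for l in self.leaves())

    def to_newick(self) -> str:
        if self.is_leaf:
            return f"{self.species}|{self.gene_id}"
        return "(" + ",".join(c.to_newick() for c in self.children) + ")"


@dataclass
class GeneTree:
    root: TreeNode
    tree_id: str = "tree"
    rooted: bool = True

    def __post_init__(self) -> None:
        leaves = self.root.leaves()
        if not leaves:
            raise ContractError("gene tree has no leaves")
        ids = [l.gene_id for l in leaves]
        if len(set(ids)) != len(ids):
            raise ContractError(f"duplicate gene ids within tree {self.tree_id}")

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def species(self) -> set[str]:
        return set(self.root.species_set())

    def to_newick(self) -> str:
        return self.root.to_newick() + ";"

    def copy(self) -> "GeneTree":
        def rec(n: TreeNode) -> TreeNode:
            m = TreeNode(children=[rec(c) for c in n.children], gene_id=n.gene_id, species=n.species)
            m.event = n.event
            return m

        return GeneTree(root=rec(self.root), tree_id=self.tree_id, rooted=self.rooted)


@dataclass
class ParsedOrthoGroup:
    """Leaf set of a maximal duplication-free subtree."""

    leaves: list[tuple[str, str]]  # (gene_id, species)
    provenance: str = ""


@dataclass
class OneToOneMap:
    """Injective cross-species gene pairs (gene in species_a, gene in species_b)."""

    pairs: list[tuple[str, str]]
    species_a: str = "Pt"
    species_b: str = "At"

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ContractError("one-to-one map is not injective in both coordinates")

    def as_dict_a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def as_dict_b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}


@dataclass
class ExtendedHomologTable:
    """Source gene -> globally unique translated target-space identifier.

    Translated ids are a bare target-species gene ID (unique source), a
    target ID with a ``.k`` suffix (k-th of several sources sharing that
    target, in lexicographic source order), or the source's own ID when no
    homolog is known.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["source_gene", "translated_id"]))

    def __post_init__(self) -> None:
        t = self.table["translated_id"]
        if t.duplicated().any():
            raise ContractError(f"translated ids not globally unique: {sorted(t[t.duplicated()].unique())[:10]}")

    def mapping(self) -> dict[str, str]:
        return dict(zip(self.table["source_gene"], self.table["translated_id"]))


# ----------------------------------------------------------------------
# Tree operations
# ----------------------------------------------------------------------

def label_duplication_nodes(tree: GeneTree) -> GeneTree:
    """Label every internal node speciation/duplication by species overlap.

    A node is a duplication iff at least two of its child subtrees share at
    least one species; polytomies are handled by pairwise child overlap.
    Returns an event-labeled copy; the input is untouched.
    """
    if not tree.rooted:
        raise ContractError(
            "tree is unrooted; apply midpoint rooting (or supply a rooted tree) before event labeling"
        )
    labeled = tree.copy()
    species_of: dict[int, frozenset[str]] = {}
    for node in labeled.root.postorder():
        if node.is_leaf:
            species_of[id(node)] = frozenset([node.species])
            continue
        child_sets = [species_of[id(c)] for c in node.children]
        overlap = any(
            s1 & s2 for s1, s2 in itertools.combinations(child_sets, 2)
        )
        node.event = DUPLICATION if overlap else SPECIATION
        species_of[id(node)] = frozenset().union(*child_sets)
    return labeled


def split_at_duplications(tree: GeneTree) -> list[ParsedOrthoGroup]:
    """Cut the labeled tree at every duplication node.

    The parsed groups are the maximal subtrees containing no duplication
    node; their leaf sets partition the tree's leaves.
    """
    dup_free: dict[int, bool] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            dup_free[id(node)] = True
        else:
            if node.event is None:
                raise ContractError("tree has unlabeled internal nodes; run label_duplication_nodes first")
            dup_free[id(node)] = node.event != DUPLICATION and all(
                dup_free[id(c)] for c in node.children
            )

    groups: list[ParsedOrthoGroup] = []

    def descend(node: TreeNode) -> None:
        if dup_free[id(node)]:
            groups.append(
                ParsedOrthoGroup(
                    leaves=[(l.gene_id, l.species) for l in node.leaves()],
                    provenance=tree.tree_id,
                )
            )
            return
        for child in node.children:
            descend(child)

    descend(tree.root)
    return groups


def extract_one_to_one(
    groups: list[ParsedOrthoGroup], species_a: str, species_b: str
) -> OneToOneMap:
    """One pair per group holding exactly one gene of each focal species.

    Genes of other species in the group are ignored. The output is sorted
    lexicographically by the species-a gene so pair order is deterministic.
    """
    pairs: list[tuple[str, str]] = []
    for group in groups:
        a_genes = sorted(g for g, s in group.leaves if s == species_a)
        b_genes = sorted(g for g, s in group.leaves if s == species_b)
        if len(a_genes) == 1 and len(b_genes) == 1:
            pairs.append((a_genes[0], b_genes[0]))
    pairs.sort()
    return OneToOneMap(pairs=pairs, species_a=species_a, species_b=species_b)


# ----------------------------------------------------------------------
# Homolog-table construction and application
# ----------------------------------------------------------------------

def build_extended_table(
    one2one: OneToOneMap,
    many_map: pd.DataFrame,
    all_source_genes: list[str],
) -> ExtendedHomologTable:
    """Merge the high-confidence one-to-one list with a many-to-one table.

    ``many_map`` must have two columns (source, target); a source gene mapped
    to two different targets is an error.  One-to-one pairs override the
    many-to-one table for their source genes.  Sources sharing a target get
    ``.1`` .. ``.k`` suffixes in lexicographic source order; sources with no
    homolog translate to their own ID.
    """
    if many_map.shape[1] != 2:
        raise ContractError("homolog table must have exactly two columns (source, target)")
    src_col, tgt_col = many_map.columns[:2]
    per_source = many_map.groupby(src_col)[tgt_col].nunique()
    bad = per_source[per_source > 1]
    if len(bad):
        raise ContractError(f"homolog table is not many-to-one; offending sources: {sorted(bad.index)[:10]}")

    target_of: dict[str, str] = dict(zip(many_map[src_col], many_map[tgt_col]))
    # high-confidence pairs take precedence
    for a_gene, b_gene in one2one.pairs:
        target_of[a_gene] = b_gene

    by_target: dict[str, list[str]] = {}
    for source in all_source_genes:
        if source in target_of:
            by_target.setdefault(target_of[source], []).append(source)

    translated: dict[str, str] = {}
    for target, sources in by_target.items():
        sources = sorted(sources)
        if len(sources) == 1:
            translated[sources[0]] = target
        else:
            for k, source in enumerate(sources, start=1):
                translated[source] = f"{target}.{k}"

    rows = [(s, translated.get(s, s)) for s in all_source_genes]
    table = pd.DataFrame(rows, columns=["source_gene", "translated_id"])
    return ExtendedHomologTable(table=table)


def apply_homolog_table(
    dataset: ExpressionDataset, table: ExtendedHomologTable
) -> ExpressionDataset:
    """Rename the dataset's gene axis through the extended table.

    Expression values are untouched; genes absent from the table keep their
    own ID; duplicate post-rename IDs are an error.
    """
    mapping = table.mapping()
    renamed = dataset.rename_genes(mapping)
    n_changed = sum(1 for old, new in zip(dataset.gene_ids, renamed.gene_ids) if old != new)
    log.info("apply_homolog_table: %d/%d gene ids translated", n_changed, dataset.n_genes)
    return renamed
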