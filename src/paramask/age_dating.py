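"""Dating duplication events from bootstrap-annotated gene trees.

The duplication that created a paralog pair is dated by the taxonomic
level of the pair's lowest common ancestor (LCA) node in a gene-family
tree: the age class is the taxon, in a reference species taxonomy, of
the LCA of all species found below that node. Classes are totally
ordered Celegans < Caenorhabditis < Bilateria < Eukaryota; pairs that
duplicated after the C. elegans - C. briggsae split ("Celegans") are the
"younger" pairs, all other dated classes are "older".

A date is confident when at least two of the three most recent tree
releases agree, or when the most recent release alone gives strong
support: bootstrap >= 70% at the LCA and at every internal node on both
leaf-to-LCA paths, except that a node may instead be a speciation node
at which no genes have been lost (its child clades have disjoint species
sets and its descendant species set is complete for its taxon). When the
two genes fall in different families and both families span human,
Drosophila and a Saccharomyces or Arabidopsis outgroup, the duplication
must predate the eukaryotic radiation and the pair is dated "Eukaryota".

Duplication versus speciation at a node is decided by species overlap:
child clades sharing at least one species imply a duplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "AGE_CLASSES",
    "AGE_CLASS_ORDER",
    "AgeCall",
    "GeneTree",
    "SpeciesTaxonomy",
    "FamilyLibrary",
    "duplication_node",
    "node_age_class",
    "support_confident",
    "date_pair",
    "infer_orthologs",
    "younger_older_label",
]

AGE_CLASSES = ("Celegans", "Caenorhabditis", "Bilateria", "Eukaryota", "Unknown")
AGE_CLASS_ORDER = {c: i for i, c in enumerate(AGE_CLASSES[:4])}

DEFAULT_CELEGANS = "Caenorhabditis_elegans"
DEFAULT_HUMAN = "Homo_sapiens"
DEFAULT_DROSOPHILA = "Drosophila_melanogaster"
DEFAULT_OUTGROUPS = frozenset(
    {"Saccharomyces_cerevisiae", "Arabidopsis_thaliana"}
)


def _parse_bootstrap(label: str | None) -> float | None:
    if label is None:
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"bootstrap {value} outside [0, 100]")
    return value


@dataclass
class SpeciesTaxonomy:
    """Rooted species tree whose internal node labels name taxa.

    The labels "Caenorhabditis", "Bilateria" and "Eukaryota" must appear
    on a root-to-C.elegans path; a clade containing only the C. elegans
    species maps to the "Celegans" class directly.
    """

    tree: dendropy.Tree
    celegans_species: str = DEFAULT_CELEGANS

    @classmethod
    def from_newick(cls, newick: str, celegans_species: str = DEFAULT_CELEGANS):
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
        return cls(tree=tree, celegans_species=celegans_species)

    @property
    def species(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def _mrca(self, species: Iterable[str]) -> dendropy.Node:
        labels = set(species)
        missing = labels - self.species
        if missing:
            raise KeyError(f"species not in taxonomy: {sorted(missing)}")
        return self.tree.mrca(taxon_labels=sorted(labels))

    def age_class_of(self, species: Iterable[str]) -> str:
        """Age class of a clade containing the given species set."""
        labels = set(species)
        if not labels:
            raise ValueError("empty species set")
        if labels == {self.celegans_species}:
            return "Celegans"
        node = self._mrca(labels)
        while node is not None:
            if node.label in AGE_CLASS_ORDER:
                return node.label
            node = node.parent_node
        raise KeyError(
            f"no labelled taxon in the taxonomy contains {sorted(labels)}"
        )

    def species_under(self, age_class: str) -> set[str]:
        """All taxonomy species below the node labelled with a class."""
        if age_class == "Celegans":
            return {self.celegans_species}
        for node in self.tree.preorder_node_iter():
            if node.label == age_class:
                return {leaf.taxon.label for leaf in node.leaf_iter()}
        raise KeyError(f"taxon {age_class!r} not found in taxonomy")


@dataclass
class GeneTree:
    """A gene-family tree with a gene -> species map and bootstraps."""

    tree: dendropy.Tree
    species_map: Mapping[str, str]
    release: str = ""

    @classmethod
    def from_newick(
        cls, newick: str, species_map: Mapping[str, str], release: str = ""
    ) -> "GeneTree":
        # read as rooted: the newick shape is authoritative and LCA-based
        # dating needs the root; a basal polytomy is handled below
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            # basal polytomy: the tree is effectively unrooted; LCA-based
            # dating needs a root, so fall back to midpoint rooting when
            # branch lengths allow it
            if all(
                e.length is not None for e in tree.preorder_edge_iter()
                if e.head_node is not root
            ):
                warnings.warn("unrooted input tree: applying midpoint rooting")
                tree.reroot_at_midpoint(update_bipartitions=False)
        gt = cls(tree=tree, species_map=dict(species_map), release=release)
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label not in gt.species_map:
                raise KeyError(f"no species for gene {leaf.taxon.label!r}")
        return gt

    @property
    def genes(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def find_leaf(self, gene: str) -> dendropy.Node:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == gene:
                return leaf
        raise KeyError(f"gene {gene!r} not in tree")

    def species_set(self, node: dendropy.Node) -> set[str]:
        return {self.species_map[leaf.taxon.label] for leaf in node.leaf_iter()}

    def bootstrap(self, node: dendropy.Node) -> float | None:
        return _parse_bootstrap(node.label)

    def is_speciation(self, node: dendropy.Node) -> bool:
        """Species-overlap criterion: children sharing a species imply a
        duplication node; disjoint child species sets, a speciation."""
        children = node.child_nodes()
        if len(children) < 2:
            return False
        seen: set[str] = set()
        for child in children:
            sp = self.species_set(child)
            if sp & seen:
                return False
            seen |= sp
        return True


@dataclass(frozen=True)
class AgeCall:
    pair_id: str
    age_class: str
    confident: bool
    basis: str | None = None

    def __post_init__(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"unknown age class {self.age_class!r}")
        if self.confident and not self.basis:
            raise ValueError("confident call requires a basis")


@dataclass
class FamilyLibrary:
    """Gene -> family membership with per-family species content."""

    gene_to_family: Mapping[str, str]
    family_species: Mapping[str, set[str]]


def duplication_node(tree: GeneTree, gene1: str, gene2: str) -> dendropy.Node:
    """Lowest common ancestor of the two genes in the gene tree."""
    for g in (gene1, gene2):
        if g not in tree.genes:
            raise KeyError(f"gene {g!r} not in tree")
    return tree.tree.mrca(taxon_labels=[gene1, gene2])


def node_age_class(
    node: dendropy.Node, tree: GeneTree, taxonomy: SpeciesTaxonomy
) -> str:
    """Taxon of the LCA, in the species taxonomy, of the node's species."""
    species = tree.species_set(node)
    return taxonomy.age_class_of(species)


def _complete_speciation(
    node: dendropy.Node, tree: GeneTree, taxonomy: SpeciesTaxonomy
) -> bool:
    """A speciation node at which no genes appear to have been lost: its
    descendant species set equals the full taxonomy species set for its
    taxonomic level."""
    if not tree.is_speciation(node):
        return False
    species = tree.species_set(node)
    try:
        taxon = taxonomy.age_class_of(species)
        expected = taxonomy.species_under(taxon)
    except KeyError:
        return False
    return species == expected


def support_confident(
    tree: GeneTree,
    gene1: str,
    gene2: str,
    taxonomy: SpeciesTaxonomy,
    min_bootstrap: float = 70.0,
) -> bool:
    """Strong-support rule for a single release.

    Requires bootstrap >= threshold at the pair's LCA, and every internal
    node on both leaf-to-LCA paths to either reach the threshold or be a
    complete speciation node. Nodes with missing bootstraps fail unless
    exempted by the speciation rule.
    """
    lca = duplication_node(tree, gene1, gene2)
    support = tree.bootstrap(lca)
    if support is None or support < min_bootstrap:
        return False
    for gene in (gene1, gene2):
        node = tree.find_leaf(gene).parent_node
        while node is not None and node is not lca:
            support = tree.bootstrap(node)
            if (support is None or support < min_bootstrap) and not (
                _complete_speciation(node, tree, taxonomy)
            ):
                return False
            node = node.parent_node
    return True


def _eukaryota_family_split(
    gene1: str,
    gene2: str,
    families: FamilyLibrary,
    human: str = DEFAULT_HUMAN,
    drosophila: str = DEFAULT_DROSOPHILA,
    outgroups: frozenset[str] = DEFAULT_OUTGROUPS,
) -> bool:
    f1 = families.gene_to_family.get(gene1)
    f2 = families.gene_to_family.get(gene2)
    if f1 is None or f2 is None or f1 == f2:
        return False
    for fam in (f1, f2):
        species = families.family_species.get(fam, set())
        if human not in species or drosophila not in species:
            return False
        if not (species & outgroups):
            return False
    return True


def date_pair(
    pair_id: str,
    gene1: str,
    gene2: str,
    release_trees: Mapping[str, GeneTree],
    taxonomy: SpeciesTaxonomy,
    families: FamilyLibrary | None = None,
    min_bootstrap: float = 70.0,
) -> AgeCall:
    """Confidence-ruled duplication date for a pair across tree releases.

    Considers the three most recent releases (by sortable release key).
    Confident when >=2 releases agree on the age class, or when the most
    recent release passes the strong-support rule; otherwise, pairs split
    across two families that each span human, Drosophila and a
    Saccharomyces/Arabidopsis outgroup date to Eukaryota. Everything else
    is Unknown.
    """
    recent = sorted(release_trees)[-3:]
    per_release: dict[str, str] = {}
    for rel in recent:
        tree = release_trees[rel]
        if gene1 in tree.genes and gene2 in tree.genes:
            node = duplication_node(tree, gene1, gene2)
            per_release[rel] = node_age_class(node, tree, taxonomy)
    votes: dict[str, int] = {}
    for cls in per_release.values():
        votes[cls] = votes.get(cls, 0) + 1
    agreed = [cls for cls, n in votes.items() if n >= 2]
    if agreed:
        # ties between agreeing classes broken by the most recent release
        if len(agreed) > 1:
            latest = max(r for r in per_release if per_release[r] in agreed)
            choice = per_release[latest]
        else:
            choice = agreed[0]
        return AgeCall(pair_id, choice, True, "multi-release-agreement")
    if recent:
        latest = recent[-1]
        if latest in per_release and support_confident(
            release_trees[latest], gene1, gene2, taxonomy, min_bootstrap
        ):
            return AgeCall(pair_id, per_release[latest], True, "strong-support")
    if families is not None and _eukaryota_family_split(gene1, gene2, families):
        return AgeCall(pair_id, "Eukaryota", True, "family-split-rule")
    return AgeCall(pair_id, "Unknown", False, None)


def infer_orthologs(
    tree: GeneTree,
    species_a: str,
    species_b: str,
    min_bootstrap: float = 70.0,
) -> list[tuple[str, str]]:
    """One-to-one ortholog pairs between two species from one gene tree.

    A leaf pair is a candidate when its LCA is a speciation node (species
    overlap rule) with bootstrap >= threshold; candidates are restricted
    to genes participating in exactly one candidate pair.
    """
    leaves_a = sorted(
        g for g in tree.genes if tree.species_map[g] == species_a
    )
    leaves_b = sorted(
        g for g in tree.genes if tree.species_map[g] == species_b
    )
    candidates: list[tuple[str, str]] = []
    for a in leaves_a:
        for b in leaves_b:
            lca = tree.tree.mrca(taxon_labels=[a, b])
            if not tree.is_speciation(lca):
                continue
            support = tree.bootstrap(lca)
            if support is None:
                # a Newick root carries no support value by construction;
                # any other unannotated node fails the threshold
                if lca is not tree.tree.seed_node:
                    continue
            elif support < min_bootstrap:
                continue
            candidates.append((a, b))
    from collections import Counter

    count_a = Counter(a for a, _ in candidates)
    count_b = Counter(b for _, b in candidates)
    return [
        (a, b) for a, b in candidates if count_a[a] == 1 and count_b[b] == 1
    ]


def younger_older_label(age_class: str) -> str | None:
    """Derived binary label: "younger" = duplicated in the C. elegans
    lineage after the C. briggsae split; "older" = any earlier dated
    class; None for Unknown."""
    if age_class == "Celegans":
        return "younger"
    if age_class in ("Caenorhabditis", "Bilateria", "Eukaryota"):
        return "older"
    return None
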