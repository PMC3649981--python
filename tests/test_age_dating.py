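"""Gene-tree duplication dating, confidence rules and ortholog inference."""

import numpy as np
import pytest

from paramask import synthetic_data
from paramask.age_dating import (
    AgeCall,
    FamilyLibrary,
    GeneTree,
    SpeciesTaxonomy,
    date_pair,
    duplication_node,
    infer_orthologs,
    node_age_class,
    support_confident,
    younger_older_label,
)

CEL = "Caenorhabditis_elegans"
CBR = "Caenorhabditis_briggsae"
CRE = "Caenorhabditis_remanei"
HSA = "Homo_sapiens"
SCE = "Saccharomyces_cerevisiae"


def gene_tree(newick, species_map, release="6"):
    return GeneTree.from_newick(newick, species_map, release)


# ---------------------------------------------------------------------------
# LCA


def test_siblings_lca_is_parent():
    gt = gene_tree("((a:1,b:1)90:1,c:1);", {"a": CEL, "b": CEL, "c": CBR})
    node = duplication_node(gt, "a", "b")
    assert {leaf.taxon.label for leaf in node.leaf_iter()} == {"a", "b"}


def test_root_children_lca_is_root():
    gt = gene_tree("((a:1,b:1)90:1,(c:1,d:1)80:1);",
                   {"a": CEL, "b": CBR, "c": CEL, "d": CBR})
    assert duplication_node(gt, "a", "c") is gt.tree.seed_node


def test_missing_gene_raises():
    gt = gene_tree("(a:1,b:1);", {"a": CEL, "b": CEL})
    with pytest.raises(KeyError):
        duplication_node(gt, "a", "zz")


def _random_binary_newick(rng, n_leaves):
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a}:1,{b}:1){int(rng.integers(50, 100))}:1")
    return nodes[0] + ";"


def _ancestor_path(gt, gene):
    node = gt.find_leaf(gene)
    path = []
    while node is not None:
        path.append(node)
        node = node.parent_node
    return path


def test_lca_matches_path_intersection_oracle():
    rng = np.random.default_rng(12)
    for _ in range(10):
        n = int(rng.integers(4, 13))
        nwk = _random_binary_newick(rng, n)
        smap = {f"L{i}": CEL for i in range(n)}
        gt = gene_tree(nwk, smap)
        g1, g2 = (f"L{i}" for i in rng.choice(n, 2, replace=False))
        # oracle: deepest node on both root-ward paths
        p1, p2 = _ancestor_path(gt, g1), _ancestor_path(gt, g2)
        common = [node for node in p1 if node in p2]
        assert duplication_node(gt, g1, g2) is common[0]


# ---------------------------------------------------------------------------
# age classes


def test_node_age_classes(taxonomy):
    gt = gene_tree(
        "(((a:1,b:1)95:1,c:1)90:1,(h:1,y:1)85:1);",
        {"a": CEL, "b": CEL, "c": CBR, "h": HSA, "y": SCE},
    )
    assert node_age_class(duplication_node(gt, "a", "b"), gt, taxonomy) == (
        "Celegans"
    )
    assert node_age_class(duplication_node(gt, "a", "c"), gt, taxonomy) == (
        "Caenorhabditis"
    )
    assert node_age_class(duplication_node(gt, "a", "h"), gt, taxonomy) == (
        "Eukaryota"  # the clade spans yeast too
    )


def test_worm_human_clade_is_bilateria(taxonomy):
    gt = gene_tree("((a:1,h:1)90:1,y:1);", {"a": CEL, "h": HSA, "y": SCE})
    assert node_age_class(duplication_node(gt, "a", "h"), gt, taxonomy) == (
        "Bilateria"
    )


def test_age_class_monotone_under_clade_enlargement(taxonomy):
    order = ["Celegans", "Caenorhabditis", "Bilateria", "Eukaryota"]
    nested = [
        {CEL},
        {CEL, CBR},
        {CEL, CBR, HSA},
        {CEL, CBR, HSA, SCE},
    ]
    classes = [taxonomy.age_class_of(s) for s in nested]
    assert classes == order


def test_unknown_species_raises(taxonomy):
    gt = gene_tree("(a:1,b:1);", {"a": CEL, "b": "Unknownia_sp"})
    with pytest.raises(KeyError):
        node_age_class(gt.tree.seed_node, gt, taxonomy)


# ---------------------------------------------------------------------------
# support rules


def test_fully_supported_path_is_confident(taxonomy):
    gt = gene_tree(
        "((a:1,c1:1)90:1,(b:1,c2:1)92:1)88;",
        {"a": CEL, "c1": CBR, "b": CEL, "c2": CBR},
    )
    assert support_confident(gt, "a", "b", taxonomy)


def test_low_lca_bootstrap_fails(taxonomy):
    gt = gene_tree("((a:1,b:1)60:1,c:1);", {"a": CEL, "b": CEL, "c": CBR})
    assert not support_confident(gt, "a", "b", taxonomy)


def test_low_path_bootstrap_fails(taxonomy):
    gt = gene_tree(
        "((a:1,c1:1)50:1,(b:1,c2:1)92:1)88;",
        {"a": CEL, "c1": CBR, "b": CEL, "c2": CBR},
    )
    assert not support_confident(gt, "a", "b", taxonomy)


def test_complete_speciation_node_exempts_low_bootstrap(taxonomy):
    # the weak node is a speciation node containing every Caenorhabditis
    # species of the taxonomy: no genes lost, so it passes regardless
    gt = gene_tree(
        "((a:1,(c1:1,r1:1)40:1)50:1,(b:1,c2:1)92:1)88;",
        {"a": CEL, "c1": CBR, "r1": CRE, "b": CEL, "c2": CBR},
    )
    assert support_confident(gt, "a", "b", taxonomy)


# ---------------------------------------------------------------------------
# date_pair


def _release_trees(class_by_release, taxonomy):
    trees = {}
    for rel, cls in class_by_release.items():
        if cls == "Celegans":
            nwk = "((a:1,b:1)90:1,c:1);"
            smap = {"a": CEL, "b": CEL, "c": CBR}
        elif cls == "Caenorhabditis":
            nwk = "((a:1,c1:1)90:1,(b:1,c2:1)92:1)88;"
            smap = {"a": CEL, "c1": CBR, "b": CEL, "c2": CBR}
        else:  # Bilateria
            nwk = "((a:1,h1:1)90:1,(b:1,h2:1)92:1)88;"
            smap = {"a": CEL, "h1": HSA, "b": CEL, "h2": HSA}
        trees[rel] = gene_tree(nwk, smap, rel)
    return trees


def test_two_of_three_release_agreement(taxonomy):
    trees = _release_trees(
        {"4": "Caenorhabditis", "5": "Caenorhabditis", "6": "Bilateria"},
        taxonomy,
    )
    call = date_pair("p", "a", "b", trees, taxonomy)
    assert call.age_class == "Caenorhabditis"
    assert call.confident and call.basis == "multi-release-agreement"


def test_single_release_strong_support(taxonomy):
    trees = _release_trees({"6": "Caenorhabditis"}, taxonomy)
    call = date_pair("p", "a", "b", trees, taxonomy)
    assert call.age_class == "Caenorhabditis"
    assert call.confident and call.basis == "strong-support"


def test_single_release_weak_support_is_unknown(taxonomy):
    gt = gene_tree("((a:1,b:1)50:1,c:1);", {"a": CEL, "b": CEL, "c": CBR})
    call = date_pair("p", "a", "b", {"6": gt}, taxonomy)
    assert call.age_class == "Unknown" and not call.confident


def test_family_split_eukaryota_rule(taxonomy):
    families = FamilyLibrary(
        gene_to_family={"a": "F1", "b": "F2"},
        family_species={
            "F1": {CEL, HSA, "Drosophila_melanogaster", SCE},
            "F2": {CEL, HSA, "Drosophila_melanogaster", "Arabidopsis_thaliana"},
        },
    )
    call = date_pair("p", "a", "b", {}, taxonomy, families=families)
    assert call.age_class == "Eukaryota"
    assert call.confident and call.basis == "family-split-rule"


def test_family_split_missing_outgroup_is_unknown(taxonomy):
    families = FamilyLibrary(
        gene_to_family={"a": "F1", "b": "F2"},
        family_species={
            "F1": {CEL, HSA, "Drosophila_melanogaster", SCE},
            "F2": {CEL, HSA},  # no Drosophila, no outgroup
        },
    )
    call = date_pair("p", "a", "b", {}, taxonomy, families=families)
    assert call.age_class == "Unknown" and not call.confident


def test_date_pair_recovers_simulated_epochs(taxonomy, small_truth):
    params, truth = small_truth
    trees = synthetic_data.emit_gene_trees(truth, params)
    recovered = 0
    for p in truth.pairs:
        release_trees = {
            rel: GeneTree.from_newick(nwk, smap, rel)
            for rel, (nwk, smap) in trees[p.pair_id].items()
        }
        call = date_pair(p.pair_id, p.gene1, p.gene2, release_trees, taxonomy)
        recovered += call.confident and call.age_class == p.age_class
    assert recovered == len(truth.pairs)


def test_low_support_fixtures_return_unknown(taxonomy, small_truth):
    params, truth = small_truth
    trees = synthetic_data.emit_gene_trees(truth, params, frac_low_support=1.0)
    for p in truth.pairs[:20]:
        release_trees = {
            rel: GeneTree.from_newick(nwk, smap, rel)
            for rel, (nwk, smap) in trees[p.pair_id].items()
        }
        call = date_pair(p.pair_id, p.gene1, p.gene2, release_trees, taxonomy)
        assert call.age_class == "Unknown" and not call.confident


# ---------------------------------------------------------------------------
# orthologs


def test_two_leaf_tree_single_ortholog_pair():
    gt = gene_tree("(a:1,b:1);", {"a": CEL, "b": CBR})
    assert infer_orthologs(gt, CEL, CBR) == [("a", "b")]


def test_root_duplication_pairs_within_clades():
    gt = gene_tree(
        "((a1:1,b1:1)90:1,(a2:1,b2:1)88:1);",
        {"a1": CEL, "b1": CBR, "a2": CEL, "b2": CBR},
    )
    assert infer_orthologs(gt, CEL, CBR) == [("a1", "b1"), ("a2", "b2")]


def test_low_bootstrap_ortholog_excluded():
    gt = gene_tree(
        "((a1:1,b1:1)60:1,(a2:1,b2:1)88:1);",
        {"a1": CEL, "b1": CBR, "a2": CEL, "b2": CBR},
    )
    assert infer_orthologs(gt, CEL, CBR) == [("a2", "b2")]


def test_orthologs_match_exhaustive_speciation_scan():
    rng = np.random.default_rng(77)
    species = [CEL, CBR]
    for _ in range(5):
        n = 10
        nwk = _random_binary_newick(rng, n)
        smap = {f"L{i}": species[int(rng.integers(2))] for i in range(n)}
        gt = gene_tree(nwk, smap)
        got = set(infer_orthologs(gt, CEL, CBR))
        # oracle: exhaustive speciation-LCA scan via ancestor paths
        cands = []
        for a in sorted(g for g, s in smap.items() if s == CEL):
            for b in sorted(g for g, s in smap.items() if s == CBR):
                p1, p2 = _ancestor_path(gt, a), _ancestor_path(gt, b)
                lca = [x for x in p1 if x in p2][0]
                kids = lca.child_nodes()
                sets = [gt.species_set(k) for k in kids]
                disjoint = all(
                    not (sets[i] & sets[j])
                    for i in range(len(sets))
                    for j in range(i + 1, len(sets))
                )
                bs = gt.bootstrap(lca)
                supported = (bs is None and lca is gt.tree.seed_node) or (
                    bs is not None and bs >= 70
                )
                if disjoint and supported:
                    cands.append((a, b))
        from collections import Counter

        ca = Counter(a for a, _ in cands)
        cb = Counter(b for _, b in cands)
        expected = {(a, b) for a, b in cands if ca[a] == 1 and cb[b] == 1}
        assert got == expected


def test_younger_older_binarization():
    assert younger_older_label("Celegans") == "younger"
    for cls in ("Caenorhabditis", "Bilateria", "Eukaryota"):
        assert younger_older_label(cls) == "older"
    assert younger_older_label("Unknown") is None
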