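"""Unit tests for MP search, Fitch reconstruction and the mutational tree,
with independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from tumevo.io_formats import DriverList
from tumevo.phylogeny import (
    GERMLINE,
    build_clone_phylogeny,
    build_mutation_tree,
    enumerate_rooted_topologies,
    fitch_score,
    map_mutations_to_branches,
    reconstruct_ancestral,
    search_mp_tree,
)
from tumevo.trees import Node, Tree

from oracles import (
    oracle_best_mp_score,
    oracle_fitch,
    oracle_min_changes,
    oracle_topologies,
    shape_to_tree,
)


def _random_genotypes(rng, n_clones, n_snvs):
    while True:
        M = rng.integers(0, 2, size=(n_clones, n_snvs)).astype(np.uint8)
        rows = {row.tobytes() for row in M}
        if len(rows) == n_clones and all(row.any() for row in M):
            return {f"c{i}": M[i] for i in range(n_clones)}


# ---------------------------------------------------------------------------
# fitch_score
# ---------------------------------------------------------------------------


def _tips_with_germline(genotypes, n):
    tips = dict(genotypes)
    tips[GERMLINE] = np.zeros(n, dtype=np.uint8)
    return tips


def test_identical_tips_score_zero():
    g = np.array([1, 0, 1], dtype=np.uint8)
    root = Node("")
    root.add_child(Node("a"))
    root.add_child(Node("b"))
    assert fitch_score({"a": g, "b": g}, Tree(root)) == 0
    # with the all-zero germline included, each shared mutation needs
    # exactly one origin
    tree = shape_to_tree(("a", "b"))
    tips = {"a": g, "b": g, GERMLINE: np.zeros(3, dtype=np.uint8)}
    assert fitch_score(tips, tree) == 2


def test_single_origin_forced():
    # tips a=0, b=0, c=1, d=1 on ((a,b),(c,d)) with germline root -> 1
    tips = {
        "a": np.array([0], dtype=np.uint8),
        "b": np.array([0], dtype=np.uint8),
        "c": np.array([1], dtype=np.uint8),
        "d": np.array([1], dtype=np.uint8),
        GERMLINE: np.array([0], dtype=np.uint8),
    }
    tree = shape_to_tree((("a", "b"), ("c", "d")))
    assert fitch_score(tips, tree) == 1


def test_fitch_score_matches_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        genotypes = _random_genotypes(rng, 5, 8)
        tips = _tips_with_germline(genotypes, 8)
        shape = next(iter(oracle_topologies(list(genotypes))))
        tree = shape_to_tree(shape)
        assert fitch_score(tips, tree) == oracle_min_changes(tree, tips)
        assert oracle_fitch(tree, tips) == oracle_min_changes(tree, tips)


# ---------------------------------------------------------------------------
# search_mp_tree
# ---------------------------------------------------------------------------


def test_two_clones_unique_topology():
    genotypes = {
        "a": np.array([1, 0], dtype=np.uint8),
        "b": np.array([1, 1], dtype=np.uint8),
    }
    tree = search_mp_tree(genotypes)
    assert sorted(tree.leaf_names()) == [GERMLINE, "a", "b"]


def test_perfect_phylogeny_score_equals_mutation_count(cherry_phylogeny):
    assert cherry_phylogeny.parsimony_length == 7
    # topology matches the nesting: a,b form a clade, c,d form a clade
    newick = cherry_phylogeny.tree.canonical_newick()
    assert "(a,b)" in newick and "(c,d)" in newick


def test_search_matches_exhaustive_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        genotypes = _random_genotypes(rng, 6, 8)
        tree = search_mp_tree(genotypes)
        tips = _tips_with_germline(genotypes, 8)
        assert fitch_score(tips, tree) == oracle_best_mp_score(genotypes)


def test_topology_count_at_five_clones():
    # (2*5 - 3)!! = 105 rooted topologies
    assert sum(1 for _ in enumerate_rooted_topologies(list("abcde"))) == 105


# ---------------------------------------------------------------------------
# reconstruct_ancestral / map_mutations_to_branches
# ---------------------------------------------------------------------------


def test_shared_mutation_on_trunk(cherry_phylogeny):
    phylo = cherry_phylogeny
    # SNV "t" present in every clone: ancestral state 1 below the root,
    # mapped to the root's clone-side child branch
    branches_with_t = [b for b, muts in phylo.branch_mutations.items()
                       if "t" in muts]
    assert len(branches_with_t) == 1
    node = phylo.tree.find(branches_with_t[0])
    assert node.parent.name == "Root"
    for name, geno in phylo.genotypes.items():
        if name not in ("Root", GERMLINE):
            assert geno[0] == 1


def test_private_mutation_on_terminal_branch(cherry_phylogeny):
    phylo = cherry_phylogeny
    assert phylo.branch_mutations["a"] == ["a"]
    for name, geno in phylo.genotypes.items():
        if name != "a":
            assert geno[3] == 0  # "a"-private SNV absent elsewhere


def test_ambiguity_resolved_to_parent_state_is_minimal():
    # cherry (a,b) with a=1, b=0 and germline 0: Fitch set at the cherry
    # ancestor is {0,1}; parent-state resolution picks 0; total changes
    # must equal the Fitch score (1), one of the enumerated minima
    tips = {
        "a": np.array([1], dtype=np.uint8),
        "b": np.array([0], dtype=np.uint8),
        GERMLINE: np.array([0], dtype=np.uint8),
    }
    tree = shape_to_tree(("a", "b"))
    genos = reconstruct_ancestral(tree, tips)
    changes = sum(
        int(genos[p.name][0] != genos[c.name][0]) for p, c in tree.edges()
    )
    assert changes == fitch_score(tips, tree) == 1
    internal = tree.root.children[1]
    assert genos[internal.name][0] == 0  # parent (root) state preferred


def test_branch_mutation_sum_equals_fitch_score():
    rng = np.random.default_rng(9)
    for _ in range(20):
        genotypes = _random_genotypes(rng, 5, 10)
        phylo = build_clone_phylogeny(genotypes, [f"S{i}" for i in range(10)])
        tips = _tips_with_germline(genotypes, 10)
        assert phylo.parsimony_length == fitch_score(tips, phylo.tree)


def test_heuristic_search_runs_beyond_exhaustive_limit():
    rng = np.random.default_rng(12)
    genotypes = _random_genotypes(rng, 9, 30)
    tree = search_mp_tree(genotypes)
    assert sorted(n for n in tree.leaf_names() if n != GERMLINE) == sorted(genotypes)


# ---------------------------------------------------------------------------
# mutation tree
# ---------------------------------------------------------------------------


def _chain_phylogeny():
    # a < b < c nested genotypes -> chain of three mutation groups
    genotypes = {
        "a": np.array([1, 1, 0, 0, 0], dtype=np.uint8),
        "b": np.array([1, 1, 1, 1, 0], dtype=np.uint8),
        "c": np.array([1, 1, 1, 1, 1], dtype=np.uint8),
    }
    return build_clone_phylogeny(genotypes, [f"S{i + 1}" for i in range(5)])


def test_chain_gives_path_of_groups():
    mtree = build_mutation_tree(_chain_phylogeny())
    assert len(mtree.nodes) == 3
    assert [n["count"] for n in mtree.nodes] == [2, 2, 1]
    assert len(mtree.roots()) == 1
    # path: each non-terminal group has exactly one child
    kids = [len(mtree.children(n["id"])) for n in mtree.nodes]
    assert sorted(kids) == [0, 1, 1]


def test_driver_on_trunk_annotated_on_first_group():
    drivers = DriverList([("S1", "TP53", "D1")])
    mtree = build_mutation_tree(_chain_phylogeny(), drivers)
    first = [n for n in mtree.nodes if "S1" in n["snvs"]]
    assert first[0]["drivers"][0]["label"] == "D1"
    assert first[0]["id"] == mtree.roots()[0]
    assert not mtree.unplaced_drivers


def test_zero_mutation_branch_contracted(cherry_phylogeny):
    phylo = cherry_phylogeny
    # remove the cd-ancestor's mutations to force a zero-length branch
    target = [b for b, muts in phylo.branch_mutations.items()
              if muts == ["cd"]][0]
    phylo.branch_mutations[target] = []
    mtree = build_mutation_tree(phylo)
    assert all(n["count"] >= 1 for n in mtree.nodes)
    # c and d groups reattach to the trunk group
    trunk_gid = [n["id"] for n in mtree.nodes if "t" in n["snvs"]][0]
    child_snvs = [mtree.node(g)["snvs"] for g in mtree.children(trunk_gid)]
    assert ["c"] in child_snvs and ["d"] in child_snvs


def test_group_counts_sum_to_parsimony_length():
    phylo = _chain_phylogeny()
    mtree = build_mutation_tree(phylo)
    assert sum(n["count"] for n in mtree.nodes) == phylo.parsimony_length
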