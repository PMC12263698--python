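import numpy as np
import pytest

from tumevo.migration import (
    ObservationTree,
    build_migration_graph,
    expand_tips,
    infer_locations,
)
from tumevo.simulate import SimulationParams, simulate_patient
from tumevo.trees import Node, Tree

from conftest import clone_set_from
from oracles import oracle_sankoff_min_migrations, oracle_site_marginals


def obs_from(tree, leaf_sites, sites):
    return ObservationTree(tree=tree, leaf_sites=leaf_sites, sites=sites)


def random_obs_tree(rng, n_leaves, n_sites):
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = [Node(n) for n in names]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        parent = Node(f"I{counter}")
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for x, n in enumerate(nodes) if x not in (i, j)] + [parent]
    sites = [f"X{k}" for k in range(n_sites)]
    leaf_sites = {n: sites[int(rng.integers(n_sites))] for n in names}
    return obs_from(Tree(nodes[0]), leaf_sites, sites)


# ---------------------------------------------------------------------------
# expand_tips
# ---------------------------------------------------------------------------


def _toy(cherry_phylogeny):
    f = np.array([
        # a     b     c     d
        [0.60, 0.00, 0.00, 0.00],
        [0.00, 0.50, 0.30, 0.00],
        [0.00, 0.00, 0.00, 0.70],
        [0.00, 0.019, 0.00, 0.40],
    ])
    samples = ["T1", "T2", "T3", "T4"]
    clones = clone_set_from(cherry_phylogeny, f, samples)
    sites = {"T1": "P", "T2": "P", "T3": "M", "T4": "M"}
    return clones, sites


def test_expand_single_sample_tip_unchanged(cherry_phylogeny):
    clones, sites = _toy(cherry_phylogeny)
    obs = expand_tips(cherry_phylogeny, clones, sites)
    leaf_names = [n.name for n in obs.tree.leaves()]
    assert "a" in leaf_names  # present in exactly one sample: no expansion
    assert obs.leaf_sites["a"] == "P"


def test_expand_multi_sample_clone(cherry_phylogeny):
    clones, sites = _toy(cherry_phylogeny)
    obs = expand_tips(cherry_phylogeny, clones, sites)
    d_leaves = [n for n in obs.tree.leaves() if n.name.startswith("d|")]
    assert {n.name for n in d_leaves} == {"d|T3", "d|T4"}
    assert all(n.length == 0 for n in d_leaves)


def test_threshold_boundary_excludes_sample(cherry_phylogeny):
    clones, sites = _toy(cherry_phylogeny)
    obs = expand_tips(cherry_phylogeny, clones, sites, presence_threshold=0.02)
    # b has f=0.019 in T4: below threshold, no leaf
    assert "b" in [n.name for n in obs.tree.leaves()]
    assert obs.leaf_sites["b"] == "P"


def test_absent_clone_raises(cherry_phylogeny):
    clones, sites = _toy(cherry_phylogeny)
    clones.f[:, 0] = 0.0
    with pytest.raises(ValueError, match="present in no sample"):
        expand_tips(cherry_phylogeny, clones, sites)


# ---------------------------------------------------------------------------
# infer_locations
# ---------------------------------------------------------------------------


def test_single_site_degenerate():
    root = Node("r")
    for i in range(3):
        root.add_child(Node(f"L{i}"))
    obs = obs_from(Tree(root), {f"L{i}": "X" for i in range(3)}, ["X"])
    post = infer_locations(obs, 0.1)
    for probs in post.marginals.values():
        np.testing.assert_allclose(probs, [1.0])
    assert all(s == "X" for s in post.map_site.values())


def test_symmetric_cherry_root_posterior():
    root = Node("r")
    root.add_child(Node("a"))
    root.add_child(Node("b"))
    obs = obs_from(Tree(root), {"a": "X", "b": "Y"}, ["X", "Y"])
    post = infer_locations(obs, p_mig=0.1)
    np.testing.assert_allclose(post.marginals["r"], [0.5, 0.5], atol=1e-12)
    assert post.map_site["r"] == "X"  # tie broken by site order
    assert "r" in post.ambiguous


def test_marginals_match_enumeration_oracle():
    rng = np.random.default_rng(0)
    for trial in range(10):
        obs = random_obs_tree(rng, n_leaves=6, n_sites=3)
        post = infer_locations(obs, p_mig=0.17)
        oracle = oracle_site_marginals(obs.tree, obs.leaf_sites, obs.sites, 0.17)
        for name, probs in post.marginals.items():
            np.testing.assert_allclose(probs, oracle[name], atol=1e-12)


def test_posterior_rows_sum_to_one():
    rng = np.random.default_rng(1)
    obs = random_obs_tree(rng, 8, 4)
    post = infer_locations(obs, 0.3)
    for probs in post.marginals.values():
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_map_at_small_pmig_matches_sankoff():
    rng = np.random.default_rng(2)
    for trial in range(10):
        obs = random_obs_tree(rng, n_leaves=7, n_sites=3)
        post = infer_locations(obs, p_mig=1e-6)
        migrations = sum(
            post.map_site[p.name] != post.map_site[c.name]
            for p, c in obs.tree.edges()
        )
        assert migrations == oracle_sankoff_min_migrations(
            obs.tree, obs.leaf_sites, obs.sites
        )


def test_invalid_pmig_rejected():
    root = Node("r")
    root.add_child(Node("a"))
    root.add_child(Node("b"))
    obs = obs_from(Tree(root), {"a": "X", "b": "X"}, ["X"])
    with pytest.raises(ValueError):
        infer_locations(obs, 0.0)


# ---------------------------------------------------------------------------
# build_migration_graph
# ---------------------------------------------------------------------------


def test_concordant_labeling_only_primary_edge():
    root = Node("r")
    for i in range(3):
        root.add_child(Node(f"L{i}", length=4))
    obs = obs_from(Tree(root), {f"L{i}": "X" for i in range(3)}, ["X"])
    post = infer_locations(obs, 0.1)
    graph = build_migration_graph(obs, post)
    assert graph.edges == []
    assert graph.origin_sites == ["X"]
    assert not graph.multimodal_origin


def test_discordant_branch_annotated_with_mutations():
    root = Node("r")
    a = root.add_child(Node("a", length=3))
    b = root.add_child(Node("b", length=5))
    c = root.add_child(Node("c", length=2))
    obs = obs_from(Tree(root), {"a": "X", "b": "Y", "c": "X"}, ["X", "Y"])
    post = infer_locations(obs, 0.1)
    graph = build_migration_graph(obs, post)
    assert post.map_site["r"] == "X"
    assert graph.edges == [
        {"source": "X", "dest": "Y", "counts": [5], "flags": []}
    ]


def test_zero_mutation_migration_flagged():
    root = Node("r")
    a = root.add_child(Node("a", length=6))
    b = root.add_child(Node("b", length=0))
    c = root.add_child(Node("c", length=4))
    obs = obs_from(Tree(root), {"a": "X", "b": "Y", "c": "X"}, ["X", "Y"])
    post = infer_locations(obs, 0.1)
    graph = build_migration_graph(obs, post)
    edge = graph.edges[0]
    assert edge["counts"] == [0]
    assert "no associated mutations" in edge["flags"]


def test_simulated_migration_history_recovered():
    recovered = 0
    total = 0
    for seed in range(10):
        prof, _, truth = simulate_patient(
            SimulationParams(seed=seed, p_true_migration=0.3)
        )
        from tumevo.evaluation import truth_observation_tree

        obs = truth_observation_tree(truth)
        post = infer_locations(obs, p_mig=0.1)
        for clone, true_site in truth.clone_sites.items():
            total += 1
            if post.map_site[clone] == true_site:
                recovered += 1
        inferred_edges = {
            (e["source"], e["dest"])
            for e in build_migration_graph(obs, post).edges
        }
        true_edges = {(src, dst) for src, dst, _, _ in truth.migration_edges}
        assert inferred_edges == true_edges, f"seed {seed}"
    assert recovered == total
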