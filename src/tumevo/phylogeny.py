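"""Maximum-parsimony clone phylogeny and mutational-tree construction.

Clone genotypes are binary vectors over SNVs.  The phylogeny is rooted by
an explicit all-zero germline outgroup tip (``Normal``); ancestral
genotypes come from Fitch small parsimony with ambiguity resolved toward
the parent state (changes placed as late as possible — mutations arise,
rarely revert) and the root forced to all-zero.

For up to 7 clones the topology search is exhaustive (10,395 rooted
topologies at 7 tips); beyond that, deterministic stepwise addition
followed by NNI hill-climbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .io_formats import DriverList
from .trees import Node, Tree

GERMLINE = "Normal"
ROOT = "Root"

# Fitch state masks: bit 0 = state 0 possible, bit 1 = state 1 possible.
_MASK = {0: 1, 1: 2}


Genotypes = dict[str, np.ndarray]


@dataclass
class ClonePhylogeny:
    """Rooted clone tree with node genotypes and per-branch mutation sets."""

    tree: Tree
    genotypes: Genotypes  # node name -> binary vector over snv_ids
    branch_mutations: dict[str, list[str]]  # child node name -> SNV ids
    snv_ids: list[str]

    @property
    def parsimony_length(self) -> int:
        return sum(len(v) for v in self.branch_mutations.values())

    def clone_names(self) -> list[str]:
        return [n for n in self.tree.leaf_names() if n != GERMLINE]


@dataclass
class MutationTree:
    """Contraction of the clone phylogeny into ordered mutation groups."""

    nodes: list[dict] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)  # (parent gid, child gid)
    unplaced_drivers: list[dict] = field(default_factory=list)

    def node(self, gid: str) -> dict:
        for n in self.nodes:
            if n["id"] == gid:
                return n
        raise KeyError(gid)

    def children(self, gid: str | None) -> list[str]:
        return [c for p, c in self.edges if p == gid]

    def roots(self) -> list[str]:
        has_parent = {c for _, c in self.edges}
        return [n["id"] for n in self.nodes if n["id"] not in has_parent]

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "edges": [list(e) for e in self.edges],
            "unplaced_drivers": self.unplaced_drivers,
        }


# ---------------------------------------------------------------------------
# Fitch small parsimony
# ---------------------------------------------------------------------------


def _postorder_masks(tree: Tree, tips: Genotypes) -> tuple[dict[int, np.ndarray], int]:
    masks: dict[int, np.ndarray] = {}
    score = 0
    for node in tree.postorder():
        if node.is_leaf:
            geno = tips[node.name]
            masks[id(node)] = np.where(geno > 0, 2, 1).astype(np.uint8)
        else:
            m = masks[id(node.children[0])].copy()
            for child in node.children[1:]:
                inter = m & masks[id(child)]
                conflict = inter == 0
                score += int(conflict.sum())
                inter[conflict] = (m | masks[id(child)])[conflict]
                m = inter
            masks[id(node)] = m
    return masks, score


def fitch_score(tips: Genotypes, tree: Tree) -> int:
    """Total Fitch parsimony changes of the tip genotypes on this topology.

    ``tips`` must cover every leaf of ``tree`` (including the germline
    outgroup if present).
    """
    missing = [n for n in tree.leaf_names() if n not in tips]
    if missing:
        raise ValueError(f"genotypes missing for leaves: {missing}")
    _, score = _postorder_masks(tree, tips)
    return score


def reconstruct_ancestral(tree: Tree, tips: Genotypes) -> Genotypes:
    """Fitch down-pass + up-pass node genotypes; root forced to all-zero.

    Ambiguous states take the parent's state, which yields one of the
    minimum-change labelings (total implied changes equal
    :func:`fitch_score`).
    """
    masks, _ = _postorder_masks(tree, tips)
    n = len(next(iter(tips.values())))
    states: dict[int, np.ndarray] = {}
    out: Genotypes = {}
    for node in tree.preorder():
        if node.parent is None:
            state = np.zeros(n, dtype=np.uint8)  # germline root
        else:
            mask = masks[id(node)]
            parent = states[id(node.parent)]
            parent_mask = np.where(parent > 0, 2, 1).astype(np.uint8)
            state = np.where(mask & parent_mask, parent, (mask == 2).astype(np.uint8))
            state = state.astype(np.uint8)
        states[id(node)] = state
        out[node.name] = state
    return out


def map_mutations_to_branches(
    tree: Tree, genotypes: Genotypes, snv_ids: list[str]
) -> dict[str, list[str]]:
    """SNV -> branch assignment: an SNV sits on branch (u, v) iff its state
    differs between v and its parent u.  Homoplasy can place one SNV on
    several branches."""
    branch: dict[str, list[str]] = {}
    for parent, child in tree.edges():
        diff = np.flatnonzero(genotypes[parent.name] != genotypes[child.name])
        branch[child.name] = [snv_ids[i] for i in diff]
    return branch


# ---------------------------------------------------------------------------
# topology enumeration and search
# ---------------------------------------------------------------------------


def _insertions(subtree, tip) -> Iterator:
    yield (subtree, tip)
    if isinstance(subtree, tuple):
        left, right = subtree
        for t in _insertions(left, tip):
            yield (t, right)
        for t in _insertions(right, tip):
            yield (left, t)


def _enumerate_shapes(labels: list[str]) -> Iterator:
    if len(labels) == 1:
        yield labels[0]
        return
    for shape in _enumerate_shapes(labels[:-1]):
        yield from _insertions(shape, labels[-1])


def _shape_to_tree(shape) -> Tree:
    """Wrap a nested-tuple clone topology with the germline root."""

    def build(s) -> Node:
        if isinstance(s, tuple):
            node = Node("")
            node.add_child(build(s[0]))
            node.add_child(build(s[1]))
            return node
        return Node(s)

    root = Node(ROOT)
    root.add_child(Node(GERMLINE))
    root.add_child(build(shape))
    return Tree(root)


def enumerate_rooted_topologies(clone_names: list[str]) -> Iterator[Tree]:
    """All rooted binary topologies over the clones, germline-rooted."""
    for shape in _enumerate_shapes(list(clone_names)):
        yield _shape_to_tree(shape)


def _clone_order(genotypes: Genotypes) -> list[str]:
    # deterministic: (mutation count, lexicographic genotype, name)
    return sorted(
        genotypes,
        key=lambda c: (int(genotypes[c].sum()), genotypes[c].tobytes(), c),
    )


EXHAUSTIVE_LIMIT = 7


def search_mp_tree(genotypes: Genotypes) -> Tree:
    """Find a maximum-parsimony germline-rooted topology for the clones.

    Exhaustive for up to :data:`EXHAUSTIVE_LIMIT` clones (ties broken by
    lexicographically smallest canonical Newick); stepwise addition plus
    NNI hill-climbing beyond that, seeded deterministically.
    """
    names = _clone_order(genotypes)
    if not names:
        raise ValueError("no clones")
    tips = dict(genotypes)
    tips[GERMLINE] = np.zeros_like(next(iter(genotypes.values())))
    if len(names) == 1:
        return _shape_to_tree(names[0])
    if len(names) <= EXHAUSTIVE_LIMIT:
        best = None
        for tree in enumerate_rooted_topologies(names):
            key = (fitch_score(tips, tree), tree.canonical_newick())
            if best is None or key < best[0]:
                best = (key, tree)
        return best[1]
    return _heuristic_search(names, tips)


def _heuristic_search(names: list[str], tips: Genotypes) -> Tree:
    shape = names[0]
    for name in names[1:]:
        best = None
        for cand in _insertions(shape, name):
            tree = _shape_to_tree(cand)
            key = (fitch_score(tips, tree), tree.canonical_newick())
            if best is None or key < best[0]:
                best = (key, cand)
        shape = best[1]
    tree = _shape_to_tree(shape)
    score = fitch_score(tips, tree)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(shape):
            cand_tree = _shape_to_tree(cand)
            cand_score = fitch_score(tips, cand_tree)
            if cand_score < score:
                shape, tree, score = cand, cand_tree, cand_score
                improved = True
                break
    return tree


def _nni_neighbors(shape) -> Iterator:
    """Nearest-neighbor interchanges on a nested-tuple rooted topology."""

    def recurse(s):
        if not isinstance(s, tuple):
            return
        left, right = s
        if isinstance(right, tuple):
            a, b = right
            yield (a, (left, b))
            yield (b, (a, left))
        if isinstance(left, tuple):
            a, b = left
            yield ((a, right), b)
            yield ((b, right), a)
        for sub in recurse(left):
            yield (sub, right)
        for sub in recurse(right):
            yield (left, sub)

    yield from recurse(shape)


# ---------------------------------------------------------------------------
# assembling a ClonePhylogeny
# ---------------------------------------------------------------------------


def _name_internal(tree: Tree) -> Tree:
    counter = 0
    for node in tree.preorder():
        if node.parent is None:
            node.name = ROOT
        elif not node.is_leaf and not node.name:
            counter += 1
            node.name = f"N{counter}"
    return tree


def build_clone_phylogeny(genotypes: Genotypes, snv_ids: list[str]) -> ClonePhylogeny:
    """Search topology, reconstruct ancestral genotypes, map mutations."""
    tree = _name_internal(search_mp_tree(genotypes))
    tips = dict(genotypes)
    tips[GERMLINE] = np.zeros(len(snv_ids), dtype=np.uint8)
    node_genotypes = reconstruct_ancestral(tree, tips)
    branch = map_mutations_to_branches(tree, node_genotypes, snv_ids)
    for parent, child in tree.edges():
        child.length = len(branch[child.name])
    return ClonePhylogeny(tree, node_genotypes, branch, snv_ids)


# ---------------------------------------------------------------------------
# mutational tree
# ---------------------------------------------------------------------------


def build_mutation_tree(phylo: ClonePhylogeny, drivers: DriverList | None = None) -> MutationTree:
    """Contract zero-mutation branches into a tree of mutation groups.

    Group ids G1..Gn are assigned in preorder; each driver is annotated
    on the group containing its SNV.  Drivers whose SNV sits on no branch
    are reported as unplaced.
    """
    mtree = MutationTree()
    counter = 0
    group_of: dict[int, str | None] = {id(phylo.tree.root): None}
    for parent, child in phylo.tree.edges():
        muts = phylo.branch_mutations.get(child.name, [])
        if muts and child.name != GERMLINE:
            counter += 1
            gid = f"G{counter}"
            mtree.nodes.append(
                {
                    "id": gid,
                    "branch": child.name,
                    "count": len(muts),
                    "snvs": list(muts),
                    "drivers": [],
                }
            )
            parent_gid = group_of[id(parent)]
            if parent_gid is not None:
                mtree.edges.append((parent_gid, gid))
            group_of[id(child)] = gid
        else:
            # zero-mutation branch contracted: child inherits the parent's group
            group_of[id(child)] = group_of[id(parent)]
    if drivers is not None:
        snv_to_gid = {
            snv: node["id"] for node in mtree.nodes for snv in node["snvs"]
        }
        for sid, gene, label in drivers.entries:
            record = {"snv_id": sid, "gene": gene, "label": label}
            gid = snv_to_gid.get(sid)
            if gid is None:
                mtree.unplaced_drivers.append(record)
            else:
                mtree.node(gid)["drivers"].append(record)
    return mtree
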