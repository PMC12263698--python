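"""Clone-composition distances between tumor samples and the NJ sample tree.

Two metrics on the clone phylogeny: abundance-weighted UniFrac (default
input to neighbor joining) and mean nearest-taxon distance (MNTD) on
presence sets.  Clone abundances are renormalized to ignore the
normal-cell fraction, so distances reflect tumor composition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .deconvolution import CloneSet
from .phylogeny import GERMLINE, ClonePhylogeny
from .trees import Node, Tree


@dataclass
class SampleDistanceMatrix:
    sample_names: list[str]
    matrix: np.ndarray
    metric: str  # "unifrac" | "mntd"


@dataclass
class SampleTree:
    tree: Tree


# ---------------------------------------------------------------------------
# weighted UniFrac
# ---------------------------------------------------------------------------


def _branch_partitions(phylo: ClonePhylogeny) -> list[tuple[float, set[str]]]:
    """(branch length, descendant clone tip set) per branch, germline
    branches excluded."""
    out = []
    for parent, child in phylo.tree.edges():
        if child.name == GERMLINE:
            continue
        tips = {
            n.name
            for n in Tree(child).preorder()
            if n.is_leaf and n.name != GERMLINE
        }
        out.append((float(child.length), tips))
    return out


def weighted_unifrac(
    phylo: ClonePhylogeny, f_a: dict[str, float], f_b: dict[str, float]
) -> float:
    """Abundance-weighted UniFrac between two clone-frequency profiles.

    d = sum_b L |p_A - p_B| / sum_b L (p_A + p_B), where p_X is the
    fraction of sample X's clone abundance descending from branch b.
    Profiles are normalized to sum 1 over present clones.
    """
    ta, tb = sum(f_a.values()), sum(f_b.values())
    if ta <= 0 or tb <= 0:
        raise ValueError("weighted UniFrac undefined for an empty sample")
    num = den = 0.0
    for length, tips in _branch_partitions(phylo):
        pa = sum(f_a.get(t, 0.0) for t in tips) / ta
        pb = sum(f_b.get(t, 0.0) for t in tips) / tb
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    if den == 0:
        return 0.0
    return num / den


def mntd(
    phylo: ClonePhylogeny, presence_a: set[str], presence_b: set[str]
) -> float:
    """Symmetric mean nearest-taxon (patristic) distance between two clone
    presence sets."""
    if not presence_a or not presence_b:
        raise ValueError("MNTD undefined for an empty presence set")
    dist = phylo.tree.patristic_distances()
    a_to_b = np.mean([min(dist[(a, b)] for b in presence_b) for a in presence_a])
    b_to_a = np.mean([min(dist[(b, a)] for a in presence_a) for b in presence_b])
    return float((a_to_b + b_to_a) / 2.0)


def sample_distance_matrix(
    phylo: ClonePhylogeny,
    clones: CloneSet,
    metric: str = "unifrac",
    presence_threshold: float = 0.02,
) -> SampleDistanceMatrix:
    names = list(clones.sample_names)
    n = len(names)
    profiles = []
    for si in range(n):
        prof = {
            c: float(clones.f[si, ci])
            for ci, c in enumerate(clones.clone_names)
            if clones.f[si, ci] > 0
        }
        if not prof:
            warnings.warn(f"sample {names[si]} has no clone abundance; excluded")
        profiles.append(prof)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if not profiles[i] or not profiles[j]:
                d = np.nan
            elif metric == "unifrac":
                d = weighted_unifrac(phylo, profiles[i], profiles[j])
            elif metric == "mntd":
                pa = {c for c, v in profiles[i].items() if v > presence_threshold}
                pb = {c for c, v in profiles[j].items() if v > presence_threshold}
                d = mntd(phylo, pa or set(profiles[i]), pb or set(profiles[j]))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            D[i, j] = D[j, i] = d
    return SampleDistanceMatrix(names, D, metric)


# ---------------------------------------------------------------------------
# neighbor joining (Saitou-Nei)
# ---------------------------------------------------------------------------


def nj_tree(dist: SampleDistanceMatrix) -> SampleTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Deterministic: ties pick the lowest index pair; negative branch
    lengths are clamped to zero with a warning.  Fewer than 3 samples
    returns a degenerate tree with a warning.
    """
    names = list(dist.sample_names)
    D = dist.matrix.astype(float).copy()
    nodes: list[Node] = [Node(n) for n in names]
    if len(names) < 3:
        warnings.warn("fewer than 3 samples: returning a degenerate tree")
        root = Node("")
        for node, d in zip(nodes, (D[0, -1] / 2.0, D[0, -1] / 2.0)):
            node.length = d
            root.add_child(node)
        return SampleTree(Tree(root))

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.6g} clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - row_sums[i] - row_sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = Node("")
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        D_next = np.zeros((len(keep) + 1, len(keep) + 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[:-1, -1] = D_next[-1, :-1] = d_new[keep]
        D = D_next
        nodes = [nodes[x] for x in keep] + [parent]
    # final 3-taxon closed form
    root = Node("")
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, length in zip(nodes, lengths):
        node.length = clamp(length)
        root.add_child(node)
    return SampleTree(Tree(root))
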