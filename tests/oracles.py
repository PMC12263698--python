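"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately implemented without the package's
vectorized code paths: pure-python sets, exhaustive enumeration, and
grid searches.
"""

import itertools

import numpy as np

from tumevo.trees import Node, Tree


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------


def oracle_min_changes(tree: Tree, tips: dict) -> int:
    """Minimum changes by exhaustive 0/1 assignment at internal nodes."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    n_chars = len(next(iter(tips.values())))
    total = 0
    for c in range(n_chars):
        best = None
        for states in itertools.product((0, 1), repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, states)}
            for n in tree.leaves():
                assign[id(n)] = int(tips[n.name][c])
            changes = sum(
                assign[id(p)] != assign[id(ch)] for p, ch in tree.edges()
            )
            best = changes if best is None else min(best, changes)
        total += best
    return total


def oracle_fitch(tree: Tree, tips: dict) -> int:
    """Set-based small parsimony, one character at a time (no numpy)."""
    n_chars = len(next(iter(tips.values())))
    score = 0

    def visit(node, c):
        nonlocal score
        if node.is_leaf:
            return {int(tips[node.name][c])}
        sets = [visit(child, c) for child in node.children]
        cur = sets[0]
        for s in sets[1:]:
            inter = cur & s
            if inter:
                cur = inter
            else:
                cur = cur | s
                score += 1
        return cur

    for c in range(n_chars):
        visit(tree.root, c)
    return score


def oracle_topologies(names):
    """Rooted binary topologies via recursive leaf-set splits (independent
    of the package's edge-insertion enumerator)."""
    names = tuple(sorted(names))
    if len(names) == 1:
        yield names[0]
        return
    first, rest = names[0], names[1:]
    for r in range(len(rest) + 1):
        for subset in itertools.combinations(rest, r):
            left = (first,) + subset
            right = tuple(x for x in rest if x not in subset)
            if not right:
                continue
            for lt in oracle_topologies(left):
                for rt in oracle_topologies(right):
                    yield (lt, rt)


def shape_to_tree(shape, germline="Normal"):
    def build(s):
        if isinstance(s, tuple):
            node = Node("")
            node.add_child(build(s[0]))
            node.add_child(build(s[1]))
            return node
        return Node(s)

    root = Node("Root")
    root.add_child(Node(germline))
    root.add_child(build(shape))
    return Tree(root)


def oracle_best_mp_score(genotypes: dict) -> int:
    """Exhaustive minimum parsimony score over all rooted topologies."""
    n = len(next(iter(genotypes.values())))
    tips = dict(genotypes)
    tips["Normal"] = np.zeros(n, dtype=np.uint8)
    best = None
    for shape in oracle_topologies(list(genotypes)):
        s = oracle_fitch(shape_to_tree(shape), tips)
        best = s if best is None else min(best, s)
    return best


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------


def oracle_site_marginals(tree: Tree, leaf_sites: dict, sites: list, p_mig: float):
    """Exact marginals by enumerating every site assignment of the free
    (non-leaf) nodes."""
    free = [n for n in tree.preorder() if not n.is_leaf]
    k = len(sites)
    idx = {s: i for i, s in enumerate(sites)}
    weights = {id(n): np.zeros(k) for n in tree.preorder()}
    total = 0.0
    for states in itertools.product(range(k), repeat=len(free)):
        assign = {id(n): s for n, s in zip(free, states)}
        for leaf in tree.leaves():
            assign[id(leaf)] = idx[leaf_sites[leaf.name]]
        w = 1.0
        for p, c in tree.edges():
            w *= 1.0 if assign[id(p)] == assign[id(c)] else p_mig
        total += w
        for n in tree.preorder():
            weights[id(n)][assign[id(n)]] += w
    return {n.name: weights[id(n)] / total for n in tree.preorder()}


def oracle_sankoff_min_migrations(tree: Tree, leaf_sites: dict, sites: list) -> int:
    """Minimum site changes (unit-cost Sankoff DP)."""
    INF = float("inf")

    def visit(node):
        if node.is_leaf:
            return {s: (0 if leaf_sites[node.name] == s else INF) for s in sites}
        costs = {s: 0.0 for s in sites}
        for child in node.children:
            child_costs = visit(child)
            for s in sites:
                costs[s] += min(
                    child_costs[t] + (0 if s == t else 1) for t in sites
                )
        return costs

    return int(min(visit(tree.root).values()))


# ---------------------------------------------------------------------------
# grid searches
# ---------------------------------------------------------------------------


def oracle_two_signature_grid(probs: np.ndarray, spectrum: np.ndarray, step=0.01):
    """Best (a, 1-a) mixture of two catalog columns by grid search."""
    s = spectrum / spectrum.sum()
    best, best_val = None, np.inf
    for a in np.arange(0.0, 1.0 + step / 2, step):
        recon = a * probs[:, 0] + (1 - a) * probs[:, 1]
        val = float(((recon - s) ** 2).sum())
        if val < best_val:
            best_val, best = val, a
    return best


# ---------------------------------------------------------------------------
# trees / distances
# ---------------------------------------------------------------------------


def random_additive_tree(rng, n_tips):
    """Random binary tree with positive lengths and its additive distance
    matrix."""
    names = [f"L{i + 1}" for i in range(n_tips)]
    nodes = [Node(n) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node("")
        for x, node in ((i, nodes[i]), (j, nodes[j])):
            node.length = float(rng.uniform(0.1, 2.0))
            parent.add_child(node)
        nodes = [n for x, n in enumerate(nodes) if x not in (i, j)] + [parent]
    root = Node("")
    for node in nodes:
        node.length = float(rng.uniform(0.1, 2.0))
        root.add_child(node)
    tree = Tree(root)
    dist = tree.patristic_distances()
    D = np.zeros((n_tips, n_tips))
    for a in range(n_tips):
        for b in range(n_tips):
            if a != b:
                D[a, b] = dist[(names[a], names[b])]
    return tree, names, D


def leaf_splits(tree: Tree) -> set:
    """Non-trivial leaf bipartitions (as frozensets of one side)."""
    all_leaves = frozenset(tree.leaf_names())
    splits = set()
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(n.name for n in Tree(node).preorder() if n.is_leaf)
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(min(side, all_leaves - side, key=sorted))
    return splits
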