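"""Metastatic cell-migration inference on the clone phylogeny.

Each clone tip is expanded into one observation leaf per tumor sample
where the clone is present; leaves carry the sample's anatomical site.
Ancestral site posteriors come from exact sum-product belief propagation
under a pairwise model where a branch weighs 1 if its endpoint sites
match and ``p_mig`` if they differ; the MAP labeling (max-product, ties
broken by fixed site order) yields migration events wherever a branch
connects differently-labeled nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .deconvolution import CloneSet
from .phylogeny import GERMLINE, ClonePhylogeny
from .trees import Node, Tree

PRIMARY = "Primary"


@dataclass
class ObservationTree:
    """Clone phylogeny with tips expanded into per-sample site leaves."""

    tree: Tree
    leaf_sites: dict[str, str]
    sites: list[str]  # deterministic order (input sample order)


@dataclass
class LocationPosterior:
    sites: list[str]
    marginals: dict[str, np.ndarray]  # node name -> probability over sites
    map_site: dict[str, str]
    ambiguous: set[str] = field(default_factory=set)


@dataclass
class MigrationGraph:
    """Directed site graph; parallel same-direction edges merged with all
    supporting-mutation counts listed."""

    sites: list[str]
    edges: list[dict] = field(default_factory=list)
    origin_sites: list[str] = field(default_factory=list)
    multimodal_origin: bool = False

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from([PRIMARY] + self.sites)
        for e in self.edges:
            g.add_edge(e["source"], e["dest"], counts=e["counts"], flags=e["flags"])
        for site in self.origin_sites:
            g.add_edge(PRIMARY, site, counts=[], flags=[])
        return g

    def to_dict(self) -> dict:
        return {
            "sites": self.sites,
            "origin_sites": self.origin_sites,
            "multimodal_origin": self.multimodal_origin,
            "edges": self.edges,
        }

    def to_dot(self) -> str:
        lines = ["digraph migration {", f'  "{PRIMARY}" [shape=diamond];']
        for site in self.sites:
            lines.append(f'  "{site}";')
        for site in self.origin_sites:
            lines.append(f'  "{PRIMARY}" -> "{site}";')
        for e in self.edges:
            label = ",".join(str(c) for c in e["counts"])
            style = ' style=dashed' if all(c == 0 for c in e["counts"]) else ""
            lines.append(
                f'  "{e["source"]}" -> "{e["dest"]}" [label="({label})"{style}];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"


def expand_tips(
    phylo: ClonePhylogeny,
    clones: CloneSet,
    sample_sites: dict[str, str],
    presence_threshold: float = 0.02,
) -> ObservationTree:
    """Expand each clone tip into one leaf per sample with f > threshold.

    Expansion branches carry zero mutations.  The germline tip is
    excluded (it has no anatomical site).
    """
    tree = phylo.tree.copy()
    # drop the germline leaf
    germ = tree.find(GERMLINE)
    germ.parent.children.remove(germ)
    leaf_sites: dict[str, str] = {}
    sites: list[str] = []
    for s in clones.sample_names:
        site = sample_sites[s]
        if site not in sites:
            sites.append(site)
    for clone_idx, clone in enumerate(clones.clone_names):
        node = tree.find(clone)
        present = [
            s for si, s in enumerate(clones.sample_names)
            if clones.f[si, clone_idx] > presence_threshold
        ]
        if not present:
            raise ValueError(f"clone {clone} present in no sample")
        if len(present) == 1 and node.is_leaf:
            leaf_sites[node.name] = sample_sites[present[0]]
        else:
            for s in present:
                leaf = node.add_child(Node(f"{clone}|{s}", length=0.0))
                leaf_sites[leaf.name] = sample_sites[s]
    return ObservationTree(tree=tree, leaf_sites=leaf_sites, sites=sites)


def _edge_weight(n_sites: int, p_mig: float) -> np.ndarray:
    W = np.full((n_sites, n_sites), p_mig)
    np.fill_diagonal(W, 1.0)
    return W


def infer_locations(obs: ObservationTree, p_mig: float = 0.1) -> LocationPosterior:
    """Exact per-node site marginals (sum-product) and a joint MAP
    labeling (max-product) on the observation tree."""
    if not 0 < p_mig < 1:
        raise ValueError("p_mig must be in (0, 1)")
    sites = obs.sites
    k = len(sites)
    idx = {s: i for i, s in enumerate(sites)}
    W = _edge_weight(k, p_mig)

    def leaf_vec(name: str) -> np.ndarray:
        v = np.zeros(k)
        v[idx[obs.leaf_sites[name]]] = 1.0
        return v

    nodes = list(obs.tree.preorder())
    # ---- sum-product -------------------------------------------------
    up: dict[int, np.ndarray] = {}      # message node -> parent
    belief: dict[int, np.ndarray] = {}  # product of children messages (x own evidence)
    for node in obs.tree.postorder():
        b = leaf_vec(node.name) if node.is_leaf else np.ones(k)
        for child in node.children:
            b = b * up[id(child)]
        b = b / b.sum()
        belief[id(node)] = b
        if node.parent is not None:
            m = W @ b
            up[id(node)] = m / m.sum()
    down: dict[int, np.ndarray] = {id(obs.tree.root): np.ones(k)}
    marginals: dict[str, np.ndarray] = {}
    for node in nodes:
        if node.parent is not None:
            u = node.parent
            ctx = down[id(u)] * (leaf_vec(u.name) if u.is_leaf else np.ones(k))
            for sib in u.children:
                if sib is not node:
                    ctx = ctx * up[id(sib)]
            d = W @ ctx
            down[id(node)] = d / d.sum()
        marg = belief[id(node)] * down[id(node)]
        marginals[node.name] = marg / marg.sum()

    # ---- max-product with backtracking -------------------------------
    # Exact ties between labelings are common when a migration chain is
    # evidenced by single leaves.  Among tied MAP labelings we prefer
    # migrations on mutation-bearing branches: discordance across a
    # zero-length branch is infinitesimally down-weighted (MAP only; the
    # marginals above use the clean pairwise model).
    W_zero = _edge_weight(k, p_mig * (1.0 - 1e-6))
    up_max: dict[int, np.ndarray] = {}
    back: dict[int, np.ndarray] = {}
    maxbelief: dict[int, np.ndarray] = {}
    for node in obs.tree.postorder():
        b = leaf_vec(node.name) if node.is_leaf else np.ones(k)
        for child in node.children:
            b = b * up_max[id(child)]
        maxbelief[id(node)] = b
        if node.parent is not None:
            W_b = W_zero if float(node.length) == 0.0 else W
            scores = W_b * b[None, :]  # scores[parent_state, own_state]
            up_max[id(node)] = scores.max(axis=1)
            back[id(node)] = scores.argmax(axis=1)
            up_max[id(node)] = up_max[id(node)] / up_max[id(node)].sum()

    map_site: dict[str, str] = {}
    ambiguous: set[str] = set()
    root = obs.tree.root
    rb = maxbelief[id(root)]
    choice = {id(root): int(np.argmax(rb))}
    if (rb >= rb.max() - 1e-12).sum() > 1:
        ambiguous.add(root.name)
    for node in nodes:
        if node.parent is not None:
            parent_state = choice[id(node.parent)]
            choice[id(node)] = int(back[id(node)][parent_state])
        map_site[node.name] = sites[choice[id(node)]]
        marg = marginals[node.name]
        if not node.is_leaf and (marg >= marg.max() - 1e-12).sum() > 1:
            ambiguous.add(node.name)
    return LocationPosterior(sites, marginals, map_site, ambiguous)


def build_migration_graph(
    obs: ObservationTree,
    posterior: LocationPosterior,
    origin_posterior_threshold: float = 0.3,
) -> MigrationGraph:
    """One graph edge per phylogeny branch whose endpoint MAP sites differ,
    annotated with that branch's mutation count (zero allowed, flagged).

    The ``Primary`` pseudo-node attaches to every site with root
    posterior above ``origin_posterior_threshold``; more than one such
    site flags a multimodal origin.
    """
    merged: dict[tuple[str, str], dict] = {}
    for parent, child in obs.tree.edges():
        src = posterior.map_site[parent.name]
        dst = posterior.map_site[child.name]
        if src == dst:
            continue
        count = int(child.length)
        e = merged.setdefault(
            (src, dst), {"source": src, "dest": dst, "counts": [], "flags": []}
        )
        e["counts"].append(count)
        if count == 0 and "no associated mutations" not in e["flags"]:
            e["flags"].append("no associated mutations")
        if parent.name in posterior.ambiguous or child.name in posterior.ambiguous:
            if "ambiguous" not in e["flags"]:
                e["flags"].append("ambiguous")
    root_marg = posterior.marginals[obs.tree.root.name]
    origin = [
        s for s, p in zip(posterior.sites, root_marg)
        if p > origin_posterior_threshold
    ]
    if not origin:
        origin = [posterior.map_site[obs.tree.root.name]]
    edges = [merged[key] for key in sorted(merged)]
    return MigrationGraph(
        sites=list(posterior.sites),
        edges=edges,
        origin_sites=origin,
        multimodal_origin=len(origin) > 1,
    )
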