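"""A small rooted-tree structure with Newick serialization.

Used for clone phylogenies, observation trees, and sample trees.  Branch
lengths are mutation counts (integers) unless a caller sets floats (the
neighbor-joining sample tree does).  Newick output writes internal node
labels and branch lengths; integers are written without a decimal point
so files are byte-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional


@dataclass
class Node:
    name: str
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree; nodes carry a name, a branch length to the parent."""

    def __init__(self, root: Node):
        self.root = root

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(name)

    def edges(self) -> list[tuple[Node, Node]]:
        """(parent, child) pairs, preorder."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    # -- distances -----------------------------------------------------

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """All pairwise leaf-to-leaf path-length sums."""
        # depth from root plus LCA via parent chains; trees here are small
        depth: dict[int, float] = {}
        parent: dict[int, Node] = {}
        for node in self.preorder():
            if node.parent is None:
                depth[id(node)] = 0.0
            else:
                depth[id(node)] = depth[id(node.parent)] + node.length
                parent[id(node)] = node.parent
        leaves = self.leaves()
        out: dict[tuple[str, str], float] = {}
        for i, a in enumerate(leaves):
            for b in leaves[i:]:
                anc = set()
                x = a
                while x is not None:
                    anc.add(id(x))
                    x = x.parent
                y = b
                while id(y) not in anc:
                    y = y.parent
                d = depth[id(a)] + depth[id(b)] - 2 * depth[id(y)]
                out[(a.name, b.name)] = d
                out[(b.name, a.name)] = d
        return out

    # -- Newick --------------------------------------------------------

    def to_newick(self, lengths: bool = True, internal_labels: bool = True) -> str:
        def fmt_len(x: float) -> str:
            if float(x).is_integer():
                return str(int(x))
            return repr(float(x))

        def render(node: Node) -> str:
            if node.is_leaf:
                s = node.name
            else:
                inner = ",".join(render(c) for c in node.children)
                label = node.name if internal_labels else ""
                s = f"({inner}){label}"
            if lengths and node.parent is not None:
                s += f":{fmt_len(node.length)}"
            return s

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string (labels and optional branch lengths)."""
        text = text.strip()
        if text.endswith(";"):
            text = text[:-1]
        pos = 0

        def parse() -> Node:
            nonlocal pos
            node = Node("")
            if text[pos] == "(":
                pos += 1
                while True:
                    node.add_child(parse())
                    if text[pos] == ",":
                        pos += 1
                        continue
                    if text[pos] == ")":
                        pos += 1
                        break
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            node.name = text[start:pos]
            if pos < len(text) and text[pos] == ":":
                pos += 1
                start = pos
                while pos < len(text) and text[pos] not in ",()":
                    pos += 1
                node.length = float(text[start:pos])
            return node

        return cls(parse())

    def canonical_newick(self) -> str:
        """Topology-only Newick with children sorted by leaf-set; used for
        deterministic tie-breaking between equally parsimonious trees."""

        def render(node: Node) -> str:
            if node.is_leaf:
                return node.name
            parts = sorted(render(c) for c in node.children)
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"


def relabel_internal(tree: Tree, prefix: str = "N") -> Tree:
    """Assign stable preorder names to unnamed internal nodes, in place."""
    counter = 0
    for node in tree.preorder():
        if not node.is_leaf and not node.name:
            counter += 1
            node.name = f"{prefix}{counter}"
    return tree


def map_nodes(tree: Tree, fn: Callable[[Node], None]) -> None:
    for node in tree.preorder():
        fn(node)
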