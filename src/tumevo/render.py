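"""Publication-style SVG renderings of pipeline results.

All figures are hand-built SVG text (no layout engine): deterministic,
valid XML, and assertable by string content.  Layout is a simple layered
tree layout with preorder y-ordering.
"""

from __future__ import annotations

import math
from xml.sax.saxutils import escape

import numpy as np

from .channels import CHANNELS, SUBSTITUTION_CLASSES
from .phylogeny import GERMLINE, ClonePhylogeny, MutationTree
from .trees import Tree

_CLASS_COLORS = {
    "C>A": "#03bcee", "C>G": "#010101", "C>T": "#e32926",
    "T>A": "#cac9c9", "T>C": "#a1ce63", "T>G": "#ebc6c4",
}
_PALETTE = ["#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3",
            "#937860", "#da8bc3", "#8c8c8c", "#ccb974", "#64b5cd"]


def _svg(width: int, height: int, body: list[str]) -> str:
    head = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">'
    )
    return "\n".join([head, *body, "</svg>\n"])


def _text(x, y, s, size=11, anchor="start", color="#000", extra=""):
    return (
        f'<text x="{x:.1f}" y="{y:.1f}" font-size="{size}" '
        f'text-anchor="{anchor}" fill="{color}" '
        f'font-family="sans-serif" {extra}>{escape(str(s))}</text>'
    )


def _line(x1, y1, x2, y2, color="#444", width=1.5, dashed=False):
    dash = ' stroke-dasharray="5,4"' if dashed else ""
    return (
        f'<line x1="{x1:.1f}" y1="{y1:.1f}" x2="{x2:.1f}" y2="{y2:.1f}" '
        f'stroke="{color}" stroke-width="{width}"{dash}/>'
    )


def _tree_layout(tree: Tree, x_step=70.0, y_step=28.0):
    """(x, y) per node: x by depth in unit steps, leaves evenly spaced in
    preorder, internals centered on their children."""
    pos: dict[int, tuple[float, float]] = {}
    leaf_y = 0.0
    depth: dict[int, int] = {}
    for node in tree.preorder():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1
    for node in tree.postorder():
        if node.is_leaf:
            leaf_y += y_step
            pos[id(node)] = (depth[id(node)] * x_step + 20, leaf_y)
        else:
            ys = [pos[id(c)][1] for c in node.children]
            pos[id(node)] = (depth[id(node)] * x_step + 20, sum(ys) / len(ys))
    return pos, leaf_y + y_step


def render_clone_tree_with_frequencies(phylo: ClonePhylogeny, clones) -> str:
    """Clone tree on the left, per-sample frequency columns on the right;
    zero frequencies are left blank."""
    for clone in clones.clone_names:
        phylo.tree.find(clone)  # raises KeyError if missing
    pos, height = _tree_layout(phylo.tree)
    body = []
    for parent, child in phylo.tree.edges():
        x1, y1 = pos[id(parent)]
        x2, y2 = pos[id(child)]
        body.append(_line(x1, y1, x1, y2))
        body.append(_line(x1, y2, x2, y2))
    max_x = max(x for x, _ in pos.values())
    for node in phylo.tree.preorder():
        x, y = pos[id(node)]
        if node.is_leaf:
            body.append(_text(x + 5, y + 4, node.name))
    col0 = max_x + 110
    col_w = 62
    for j, sample in enumerate(clones.sample_names):
        body.append(_text(col0 + j * col_w, 16, sample, size=10, anchor="middle"))
    for i, clone in enumerate(clones.clone_names):
        node = phylo.tree.find(clone)
        _, y = pos[id(node)]
        for j in range(len(clones.sample_names)):
            v = clones.f[j, i]
            if v > 0:
                body.append(
                    _text(col0 + j * col_w, y + 4, f"{v:.2f}", size=10,
                          anchor="middle")
                )
    width = int(col0 + col_w * len(clones.sample_names) + 30)
    return _svg(width, int(height + 20), body)


def _mutation_tree_layout(mtree: MutationTree, x_step=110.0, y_step=60.0):
    pos: dict[str, tuple[float, float]] = {}
    y = [0.0]

    def place(gid: str, depth: int):
        kids = sorted(mtree.children(gid))
        if not kids:
            y[0] += y_step
            pos[gid] = (depth * x_step + 70, y[0])
            return
        for k in kids:
            place(k, depth + 1)
        ys = [pos[k][1] for k in kids]
        pos[gid] = (depth * x_step + 70, sum(ys) / len(ys))

    for root in sorted(mtree.roots()):
        place(root, 0)
    return pos, y[0] + y_step


def render_mutation_tree(mtree: MutationTree) -> str:
    """Group circles with mutation counts; blue dots time the drivers."""
    pos, height = _mutation_tree_layout(mtree)
    body = []
    genes = []
    for p, c in mtree.edges:
        x1, y1 = pos[p]
        x2, y2 = pos[c]
        body.append(_line(x1, y1, x2, y2, color="#666"))
    for node in mtree.nodes:
        x, yy = pos[node["id"]]
        body.append(
            f'<circle cx="{x:.1f}" cy="{yy:.1f}" r="22" fill="#f4f4f4" '
            f'stroke="#333"/>'
        )
        body.append(_text(x, yy - 3, node["id"], size=10, anchor="middle"))
        body.append(_text(x, yy + 10, node["count"], size=10, anchor="middle"))
        for di, drv in enumerate(node["drivers"]):
            dx, dy = x - 28, yy - 16 + 14 * di
            body.append(f'<circle cx="{dx:.1f}" cy="{dy:.1f}" r="4" fill="#1f4fd8"/>')
            body.append(_text(dx - 7, dy + 4, drv["label"], size=9, anchor="end",
                              color="#1f4fd8"))
            genes.append(f'{drv["label"]}: {drv["gene"]}')
    for gi, g in enumerate(genes):
        body.append(_text(10, 16 + 13 * gi, g, size=10, color="#1f4fd8"))
    width = int(max((x for x, _ in pos.values()), default=200) + 120)
    return _svg(width, int(height + 20), body)


def render_signature_layers(mtree, activities, spectra, drivers=None) -> dict[str, str]:
    """Figure set: an activity overview (stacked bars per edge) plus one
    96-channel spectrum barplot per branch with driver channels marked."""
    out: dict[str, str] = {}
    act_by_branch = {a.branch: a for a in activities}
    sig_names = sorted({s for a in activities for s in a.retained})
    color = {s: _PALETTE[i % len(_PALETTE)] for i, s in enumerate(sig_names)}

    pos, height = _mutation_tree_layout(mtree, x_step=150.0, y_step=80.0)
    body = []
    for p, c in mtree.edges:
        x1, y1 = pos[p]
        x2, y2 = pos[c]
        body.append(_line(x1, y1, x2, y2, color="#999"))
    for node in mtree.nodes:
        gid = node["id"]
        x, yy = pos[gid]
        body.append(_text(x, yy - 28, gid, size=10, anchor="middle"))
        act = act_by_branch.get(gid)
        if act is None or not act.retained:
            body.append(_text(x, yy, "(no fit)", size=9, anchor="middle"))
            continue
        x0 = x - 30
        for sig in sorted(act.retained):
            w = 60.0 * act.activities.get(sig, 0.0)
            body.append(
                f'<rect x="{x0:.1f}" y="{yy - 8:.1f}" width="{w:.1f}" '
                f'height="16" fill="{color.get(sig, "#333")}"/>'
            )
            x0 += w
        body.append(_text(x, yy + 24,
                          "/".join(sorted(act.retained)), size=8, anchor="middle"))
    for i, sig in enumerate(sig_names):
        body.append(f'<rect x="10" y="{8 + 14 * i}" width="10" height="10" '
                    f'fill="{color[sig]}"/>')
        body.append(_text(24, 17 + 14 * i, sig, size=10))
    width = int(max((x for x, _ in pos.values()), default=200) + 160)
    out["signature_overview"] = _svg(width, int(height + 30), body)

    driver_by_snv = {}
    if drivers is not None:
        driver_by_snv = {sid: label for sid, _, label in drivers.entries}
    for spec in spectra:
        if spec.counts.sum() == 0:
            out[f"spectrum_{spec.branch}"] = _svg(
                300, 60, [_text(10, 30, f"{spec.branch}: no mutations")]
            )
            continue
        body = []
        bar_w, h0 = 7, 150
        peak = spec.counts.max()
        for ci, c in enumerate(spec.counts):
            cls = SUBSTITUTION_CLASSES[ci // 16]
            x = 40 + ci * bar_w
            bh = h0 * (c / peak)
            body.append(
                f'<rect x="{x}" y="{30 + h0 - bh:.1f}" width="{bar_w - 1}" '
                f'height="{bh:.1f}" fill="{_CLASS_COLORS[cls]}"/>'
            )
        for k, cls in enumerate(SUBSTITUTION_CLASSES):
            body.append(_text(40 + (k * 16 + 8) * bar_w, 20, cls, size=11,
                              anchor="middle"))
        for ci in spec.driver_channels:
            x = 40 + ci * bar_w + bar_w / 2
            body.append(_line(x, 30, x, 30 + h0, color="#1f4fd8", width=1,
                              dashed=True))
            body.append(_text(x, 30 + h0 + 26, CHANNELS[ci], size=8,
                              anchor="middle", color="#1f4fd8"))
        body.append(_text(40, 30 + h0 + 14, spec.branch, size=11))
        out[f"spectrum_{spec.branch}"] = _svg(40 + 96 * bar_w + 40, h0 + 70, body)
    return out


def render_migration_graph(graph) -> str:
    """Sites on a circle, Primary at center; edges annotated "(n)" when
    n > 0, dashed and unannotated when every supporting count is zero."""
    sites = list(graph.sites)
    n = max(len(sites), 1)
    cx, cy, r = 230.0, 200.0, 150.0
    pos = {"Primary": (cx, cy)}
    for i, s in enumerate(sites):
        a = 2 * math.pi * i / n - math.pi / 2
        pos[s] = (cx + r * math.cos(a), cy + r * math.sin(a))
    body = []
    for site in graph.origin_sites:
        x1, y1 = pos["Primary"]
        x2, y2 = pos[site]
        body.append(_line(x1, y1, x2, y2, color="#777"))
    for e in graph.edges:
        x1, y1 = pos[e["source"]]
        x2, y2 = pos[e["dest"]]
        zero = all(c == 0 for c in e["counts"])
        body.append(_line(x1, y1, x2, y2, color="#b03a2e", dashed=zero))
        # arrowhead
        ux, uy = x2 - x1, y2 - y1
        norm = math.hypot(ux, uy) or 1.0
        ux, uy = ux / norm, uy / norm
        hx, hy = x2 - 24 * ux, y2 - 24 * uy
        body.append(
            f'<polygon points="{hx + 5 * uy:.1f},{hy - 5 * ux:.1f} '
            f'{hx - 5 * uy:.1f},{hy + 5 * ux:.1f} '
            f'{hx + 9 * ux:.1f},{hy + 9 * uy:.1f}" fill="#b03a2e"/>'
        )
        if not zero:
            label = ",".join(str(c) for c in e["counts"] if c > 0)
            body.append(_text((x1 + x2) / 2 + 6, (y1 + y2) / 2 - 4,
                              f"({label})", size=10, color="#b03a2e"))
    for name, (x, y) in pos.items():
        body.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="20" fill="#fff" '
                    f'stroke="#333"/>')
        body.append(_text(x, y + 4, name, size=9, anchor="middle"))
    return _svg(470, 410, body)


def render_sample_tree(stree) -> str:
    """Unrooted sample tree drawn with an equal-angle radial layout."""
    tree = stree.tree
    leaves = tree.leaves()
    counts: dict[int, int] = {}
    for node in tree.postorder():
        counts[id(node)] = 1 if node.is_leaf else sum(
            counts[id(c)] for c in node.children
        )
    pos: dict[int, tuple[float, float]] = {id(tree.root): (250.0, 220.0)}
    total = max(counts[id(tree.root)], 1)

    def assign(node, angle_lo, angle_hi):
        x0, y0 = pos[id(node)]
        a = angle_lo
        for child in node.children:
            frac = counts[id(child)] / total
            a_child = a + frac * (angle_hi - angle_lo)
            mid = (a + a_child) / 2
            step = 45 + 160 * float(child.length) / (_max_len(tree) or 1)
            pos[id(child)] = (x0 + step * math.cos(mid), y0 + step * math.sin(mid))
            assign(child, a, a_child)
            a = a_child

    assign(tree.root, 0.0, 2 * math.pi)
    body = []
    for parent, child in tree.edges():
        x1, y1 = pos[id(parent)]
        x2, y2 = pos[id(child)]
        body.append(_line(x1, y1, x2, y2))
    for leaf in leaves:
        x, y = pos[id(leaf)]
        body.append(_text(x + 4, y - 4, leaf.name, size=10))
    return _svg(520, 460, body)


def _max_len(tree: Tree) -> float:
    return max((float(n.length) for n in tree.preorder() if n.parent is not None),
               default=1.0)
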