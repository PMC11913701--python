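"""Distance-based trees: neighbor joining, midpoint rooting, Newick round-trip.

The tree stage of the pipeline: percent identities become p-distances
(``d = 1 - identity/100``), the distance matrix becomes an unrooted
neighbor-joining tree, and the tree is rooted at the midpoint of the longest
leaf-to-leaf path — the point equidistant from the two most distant taxa —
unless the user asks for the unrooted form. Trees are scikit-bio
``TreeNode`` objects throughout, so Newick serialization and standard
traversals come with the container.
"""

from __future__ import annotations

import io
import math
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode


class NewickError(ValueError):
    """Raised when Newick text cannot be parsed."""


def distance_from_pim(pim, correction: str | None = None) -> DistanceMatrix:
    """Convert a percent-identity matrix to p-distances ``1 - pim/100``.

    ``correction="poisson"`` applies ``-ln(1 - p)`` (capped at p = 0.95) for
    multiple substitutions; the default is the plain p-distance.
    """
    d = 1.0 - np.asarray(pim.values, dtype=float) / 100.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    if correction == "poisson":
        d = -np.log(1.0 - np.minimum(d, 0.95))
        np.fill_diagonal(d, 0.0)
    elif correction is not None:
        raise ValueError(f"unknown distance correction {correction!r}")
    return DistanceMatrix(d, ids=list(pim.labels))


def _validate(dm: DistanceMatrix) -> None:
    if np.any(np.asarray(dm.data) < 0):
        raise ValueError("distance matrix has negative entries")


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion; branch lengths
    come from the standard two-point formulas, with negative lengths clamped
    to zero and the deficit moved to the sibling branch so the pair's total
    is conserved. Q-ties are broken by the lowest (row, column) index pair in
    the current matrix, so the output is bitwise reproducible. The result is
    unrooted, represented with a trifurcating top node (``size >= 3``); two
    taxa yield a single edge split evenly.
    """
    _validate(dm)
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    if n == 2:
        half = float(dm[ids[0], ids[1]]) / 2.0
        return TreeNode(children=[TreeNode(name=ids[0], length=half),
                                  TreeNode(name=ids[1], length=half)])
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < Q[best] - 1e-12:
                    best = (a, b)
        a, b = best
        d_ab = sub[a, b]
        la = d_ab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d_ab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        i, j = active[a], active[b]
        nodes[i].length = la
        nodes[j].length = lb
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every remaining cluster
        new_d = np.zeros(D.shape[0])
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            new_d[k] = max((sub[a, c] + sub[b, c] - d_ab) / 2.0, 0.0)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d
        D[:-1, -1] = new_d
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]
    a, b, c = active
    d_ab, d_ac, d_bc = D[a, b], D[a, c], D[b, c]
    nodes[a].length = max((d_ab + d_ac - d_bc) / 2.0, 0.0)
    nodes[b].length = max((d_ab + d_bc - d_ac) / 2.0, 0.0)
    nodes[c].length = max((d_ac + d_bc - d_ab) / 2.0, 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def _adjacency(tree: TreeNode) -> tuple[dict[int, list[tuple[int, float]]],
                                        dict[int, str | None]]:
    """Undirected weighted adjacency with degree-2 internal nodes contracted."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}

    def add(u: int, v: int, w: float) -> None:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    for node in tree.traverse(include_self=True):
        names[id(node)] = node.name
        adj.setdefault(id(node), [])
        for child in node.children:
            add(id(node), id(child), float(child.length or 0.0))
    # contract pass-through nodes (e.g. an old degree-2 root)
    changed = True
    while changed:
        changed = False
        for u, nb in list(adj.items()):
            if len(nb) == 2 and names[u] is None:
                (v, w1), (x, w2) = nb
                adj[v] = [(t, w) for t, w in adj[v] if t != u] + [(x, w1 + w2)]
                adj[x] = [(t, w) for t, w in adj[x] if t != u] + [(v, w1 + w2)]
                del adj[u]
                changed = True
                break
    return adj, names


def _farthest_leaf(adj, names, start: int) -> tuple[int, float, list[int]]:
    """DFS: the farthest leaf from ``start`` (ties broken by leaf name)."""
    best: tuple[int, float, list[int]] | None = None
    stack = [(start, -1, 0.0, [start])]
    while stack:
        u, parent, dist, path = stack.pop()
        nb = [t for t, _ in adj[u] if t != parent]
        if not nb and u != start:
            name = names[u] or ""
            better = (best is None or dist > best[1] + 1e-15
                      or (abs(dist - best[1]) <= 1e-15 and name < (names[best[0]] or "")))
            if better:
                best = (u, dist, path)
        for t, w in sorted(adj[u], key=lambda e: (names[e[0]] or "", e[1])):
            if t != parent:
                stack.append((t, u, dist + w, path + [t]))
    assert best is not None, "no leaf reachable from start"
    return best


def _build_rooted(adj, names, root_children: list[tuple[int, float, int]]) -> TreeNode:
    def build(u: int, parent: int, length: float) -> TreeNode:
        kids = [build(t, u, w) for t, w in adj[u] if t != parent]
        return TreeNode(name=names[u], length=length, children=kids or None)

    return TreeNode(children=[build(u, parent, w) for u, w, parent in root_children])


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    The root is inserted on the path between the two most distant taxa,
    equidistant from both; if the midpoint falls exactly on an existing
    internal node the tree is rooted there. Total branch length is conserved.
    """
    tips = sorted(tree.tips(), key=lambda t: t.name or "")
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    adj, names = _adjacency(tree)
    start = id(tips[0])
    u, _, _ = _farthest_leaf(adj, names, start)
    v, diameter, path = _farthest_leaf(adj, names, u)
    half = diameter / 2.0
    # walk the u -> v path until the cumulative distance reaches half
    cum = 0.0
    for x, y in zip(path, path[1:]):
        w = next(wt for t, wt in adj[x] if t == y)
        if cum + w >= half - 1e-12:
            into_edge = half - cum
            if into_edge <= 1e-12 and len(adj[x]) > 1:  # midpoint on node x
                children = [(t, wt, x) for t, wt in adj[x]]
                return _build_rooted(adj, names, children)
            if abs(cum + w - half) <= 1e-12 and len(adj[y]) > 1:  # on node y
                children = [(t, wt, y) for t, wt in adj[y]]
                return _build_rooted(adj, names, children)
            # split edge (x, y): the new root hangs x's side and y's side
            adj[x] = [(t, wt) for t, wt in adj[x] if t != y]
            adj[y] = [(t, wt) for t, wt in adj[y] if t != x]
            return _build_rooted(adj, names, [(x, into_edge, y), (y, w - into_edge, x)])
        cum += w
    raise AssertionError("midpoint not found on diameter path")  # pragma: no cover


def total_branch_length(tree: TreeNode) -> float:
    return sum(float(n.length or 0.0) for n in tree.traverse(include_self=False))


def leaf_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """All pairwise leaf-to-leaf path-length distances."""
    return tree.tip_tip_distances()


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Serialize to Newick; branch lengths rounded to ``precision`` significant digits."""
    clone = tree.copy()
    for node in clone.traverse(include_self=False):
        if node.length is not None:
            node.length = float(f"%.{precision}g" % node.length)
    buf = io.StringIO()
    clone.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> TreeNode:
    """Parse Newick text; malformed input raises :class:`NewickError`."""
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sniffer chatter on odd input
            return TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise NewickError(f"invalid Newick: {exc}") from None
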