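"""Neighbor-joining tree construction and midpoint rooting.

Classic NJ (Saitou & Nei, with the Studier-Keppler Q criterion): repeatedly
join the pair (i, j) minimizing

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),

computing branch lengths from the standard formulas, until three nodes
remain, which are joined in a final trifurcation. The result is an unrooted
tree. Ties in Q are broken by the lexicographically smallest (label_i,
label_j) pair and negative branch-length estimates are clamped to zero (the
clamped deficit is logged), so trees are reproducible bit for bit.

Rooted views for the rooted tree metrics are produced by midpoint rooting:
the root is placed halfway along the longest leaf-to-leaf path, ties broken
by the lexicographically smallest leaf pair.
"""

from __future__ import annotations

import itertools
import logging

import dendropy
import numpy as np

from .distances import DistanceMatrix, MatrixError

logger = logging.getLogger(__name__)


def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a labeled distance matrix."""
    n = m.n
    if n < 3:
        raise MatrixError(f"neighbor joining needs at least 3 taxa, got {n}")

    taxa = dendropy.TaxonNamespace([str(l) for l in m.labels])
    tree = dendropy.Tree(taxon_namespace=taxa)

    d = m.values.copy()
    nodes: list[dendropy.Node] = []
    # sort key per active node: smallest leaf label in its subtree
    keys: list[str] = []
    for label in m.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(str(label)))
        nodes.append(node)
        keys.append(str(label))

    clamped = 0.0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped += -x
            return 0.0
        return x

    active = list(range(n))
    while len(active) > 3:
        na = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a, b in zip(*np.where(np.isclose(q, qmin, rtol=0.0, atol=1e-12))):
            if a >= b:
                continue
            i, j = active[a], active[b]
            key = tuple(sorted((keys[i], keys[j])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]

        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (na - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamp(li)
        nodes[j].edge.length = _clamp(lj)

        # distances from the new node u: d(u, k) = (d(i,k) + d(j,k) - d(i,j)) / 2
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        u = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[u, :u] = new_row
        d[:u, u] = new_row
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [u]

    # final trifurcation
    a, b, c = active
    center = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        length = 0.5 * (d[x, y] + d[x, z] - d[y, z])
        center.add_child(nodes[x])
        nodes[x].edge.length = _clamp(length)
    tree.seed_node = center
    tree.is_rooted = False
    if clamped > 0.0:
        logger.info("neighbor_joining: clamped negative branch lengths (total deficit %.6g)", clamped)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _leaf_paths(tree: dendropy.Tree):
    """Patristic distance and node path between every leaf pair."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    # build undirected adjacency
    adj: dict[int, list[tuple[int, float, object]]] = {}
    nodes = list(tree.preorder_node_iter())
    for node in nodes:
        for ch in node.child_nodes():
            w = ch.edge.length if ch.edge.length is not None else 0.0
            adj.setdefault(id(node), []).append((id(ch), w, ch))
            adj.setdefault(id(ch), []).append((id(node), w, node))
    byid = {id(nd): nd for nd in nodes}
    return leaves, adj, byid


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a rooted copy of ``tree`` with the root at the midpoint of the
    longest leaf-to-leaf path (lexicographic leaf-pair tie-break).

    If every branch length is zero (or missing) the tree is rooted at the
    first internal node instead, with a log message.
    """
    tree = tree.clone(depth=1)
    leaves, adj, byid = _leaf_paths(tree)
    if len(leaves) < 2:
        raise MatrixError("midpoint rooting needs at least 2 leaves")

    # BFS from each leaf recording distance and predecessor
    best = None  # (-dist, labelA, labelB, pathnodes)
    for src in leaves:
        dist = {id(src): 0.0}
        prev = {id(src): None}
        stack = [id(src)]
        while stack:
            u = stack.pop()
            for v, w, _ in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        for dst in leaves:
            if dst is src:
                continue
            pair = tuple(sorted((src.taxon.label, dst.taxon.label)))
            cand = (-dist[id(dst)], pair[0], pair[1])
            if best is None or cand < best[0]:
                if pair[0] == src.taxon.label or pair[0] == dst.taxon.label:
                    path = []
                    u = id(dst)
                    while u is not None:
                        path.append(u)
                        u = prev[u]
                    # path runs dst -> src; orient from lexicographically
                    # smaller leaf for a deterministic midpoint side
                    if pair[0] == dst.taxon.label:
                        ordered = path
                    else:
                        ordered = path[::-1]
                    best = (cand, ordered)

    (neg_total, _, _), path = best
    total = -neg_total
    if total <= 0.0:
        logger.info("midpoint_root: all path lengths zero; rooting at first internal node")
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                tree.reroot_at_node(node, update_bipartitions=True,
                                    suppress_unifurcations=True)
                tree.is_rooted = True
                return tree
        raise MatrixError("tree has no internal node")

    half = total / 2.0
    # walk along the path until the midpoint falls within an edge
    edge_len = {}
    acc = 0.0
    for u, v in itertools.pairwise(path):
        nu, nv = byid[u], byid[v]
        # edge between nu and nv: child is whichever has the other as parent
        child = nv if nv.parent_node is nu else nu
        w = child.edge.length or 0.0
        if acc + w >= half - 1e-12:
            # midpoint sits on this edge, at (half - acc) from node u
            offset_from_child_end = None
            # distances measured from u along edge toward v
            from_u = half - acc
            if child is nv:
                child_side = w - from_u  # distance from child (v) end
            else:
                child_side = from_u
            child_side = min(max(child_side, 0.0), w)
            tree.reroot_at_edge(
                child.edge,
                length1=w - child_side,
                length2=child_side,
                update_bipartitions=False,
            )
            tree.is_rooted = True
            tree.update_bipartitions(suppress_unifurcations=False)
            return tree
        acc += w
    raise AssertionError("midpoint not found on path")  # pragma: no cover


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(
        (e.length or 0.0) for e in tree.preorder_edge_iter() if e.head_node.parent_node
    )
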