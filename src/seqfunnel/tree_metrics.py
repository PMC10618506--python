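"""Nine phylogenetic tree-comparison metrics.

These validate matrix-level rankings at the tree level. Unrooted metrics
(Robinson-Foulds, matching pair, quartet, path difference, cophenetic L2)
are computed on the unrooted view of each tree; rooted metrics (triples,
matching cluster, nodal splitted, MAST) are computed on rooted views —
trees that arrive unrooted are midpoint-rooted first.

Conventions follow the TreeCmp tool family: RF is the halved symmetric
difference of nontrivial splits; matching metrics use minimum-weight
perfect matchings (Hungarian algorithm) over splits/clusters with
symmetric-difference-style costs; MAST distance is the leaf count minus the
maximum agreement subtree size; nodal splitted is the L2 norm over ordered
leaf pairs of the edge count from a leaf up to the pair's LCA.

Algorithms are exact and sized for desk-scale trees (up to a few hundred
taxa); the quartet metric enumerates sums over all C(n, 4) leaf subsets via
the topological path matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

from .njtree import midpoint_root

__all__ = [
    "MetricResult",
    "METRIC_NAMES",
    "rf_distance",
    "triples_distance",
    "quartet_distance",
    "mast_distance",
    "cophenetic_l2",
    "path_difference",
    "matching_cluster",
    "matching_pair",
    "nodal_splitted",
    "compare_all",
]

METRIC_NAMES = (
    "triples",
    "rf",
    "matching_pair",
    "nodal_splitted",
    "matching_cluster",
    "mast",
    "cophenetic",
    "quartet",
    "path_difference",
)

_ROOTED_METRICS = frozenset({"triples", "matching_cluster", "nodal_splitted", "mast"})


class TreeComparisonError(ValueError):
    """Incompatible tree pair (leaf-set mismatch, too few taxa)."""


@dataclass(frozen=True)
class MetricResult:
    metric: str
    value: float
    normalized: float | None
    n_taxa: int


# ---------------------------------------------------------------------------
# tree views
# ---------------------------------------------------------------------------

class _TreeView:
    """Precomputed structures for one tree over a fixed leaf ordering.

    Leaf sets are bitmasks over ``labels`` (sorted leaf labels); ``full`` is
    the all-leaves mask. The rooted structures (clusters, LCA depths) treat
    the tree's seed node as the root; for unrooted use, a degree-two seed
    node is suppressed when building splits and path matrices.
    """

    def __init__(self, tree: dendropy.Tree, labels: tuple[str, ...]):
        self.labels = labels
        self.n = len(labels)
        self.index = {l: i for i, l in enumerate(labels)}
        self.full = (1 << self.n) - 1
        self.tree = tree

        # postorder leafset masks per node
        self.mask: dict[int, int] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self.mask[id(node)] = 1 << self.index[node.taxon.label]
            else:
                m = 0
                for ch in node.child_nodes():
                    m |= self.mask[id(ch)]
                self.mask[id(node)] = m

    # -- unrooted structures ------------------------------------------------

    def splits(self) -> set[int]:
        """Canonical nontrivial splits (side not containing leaf 0)."""
        out = set()
        for node in self.tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            m = self.mask[id(node)]
            if m & 1:
                m = self.full & ~m
            pc = m.bit_count()
            if 2 <= pc <= self.n - 2:
                out.add(m)
        return out

    def _adjacency(self, topological: bool):
        adj: dict[int, list[tuple[int, float]]] = {}
        for node in self.tree.preorder_node_iter():
            for ch in node.child_nodes():
                w = 1.0 if topological else (ch.edge.length or 0.0)
                adj.setdefault(id(node), []).append((id(ch), w))
                adj.setdefault(id(ch), []).append((id(node), w))
        # suppress a degree-2 seed node for the unrooted view
        seed = id(self.tree.seed_node)
        if len(adj.get(seed, ())) == 2:
            (a, wa), (b, wb) = adj[seed]
            adj[a] = [(x, w) for x, w in adj[a] if x != seed] + [(b, wa + wb)]
            adj[b] = [(x, w) for x, w in adj[b] if x != seed] + [(a, wa + wb)]
            del adj[seed]
        return adj

    def path_matrix(self, topological: bool) -> np.ndarray:
        """Leaf-by-leaf path lengths (edge counts or branch-length sums)."""
        adj = self._adjacency(topological)
        leaf_ids = {}
        for lf in self.tree.leaf_node_iter():
            leaf_ids[id(lf)] = self.index[lf.taxon.label]
        out = np.zeros((self.n, self.n))
        for src, i in leaf_ids.items():
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj.get(u, ()):
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for dst, j in leaf_ids.items():
                out[i, j] = dist[dst]
        return out

    # -- rooted structures --------------------------------------------------

    def clusters(self) -> list[int]:
        """Nontrivial clusters: leaf sets of internal nodes, excluding the
        full leaf set and singletons."""
        out = []
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                continue
            m = self.mask[id(node)]
            if 2 <= m.bit_count() <= self.n - 1:
                out.append(m)
        return out

    def depths(self) -> tuple[np.ndarray, np.ndarray]:
        """(leaf depth vector, pairwise LCA depth matrix), in edge counts."""
        depth: dict[int, int] = {id(self.tree.seed_node): 0}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[id(node)] = depth[id(node.parent_node)] + 1
        leaf_depth = np.zeros(self.n)
        for lf in self.tree.leaf_node_iter():
            leaf_depth[self.index[lf.taxon.label]] = depth[id(lf)]
        lca = np.zeros((self.n, self.n))
        for node in self.tree.postorder_node_iter():
            kids = node.child_nodes()
            if not kids:
                continue
            d = depth[id(node)]
            masks = [self.mask[id(c)] for c in kids]
            for (ma, mb) in itertools.combinations(masks, 2):
                ia = _mask_indices(ma)
                ib = _mask_indices(mb)
                for i in ia:
                    lca[i, ib] = d
                    lca[np.ix_(ib, [i])] = d
        np.fill_diagonal(lca, leaf_depth)
        return leaf_depth, lca


def _mask_indices(mask: int) -> list[int]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return out


def _prepare(t1: dendropy.Tree, t2: dendropy.Tree, metric: str, min_n: int):
    l1 = sorted(lf.taxon.label for lf in t1.leaf_node_iter())
    l2 = sorted(lf.taxon.label for lf in t2.leaf_node_iter())
    if l1 != l2:
        only1 = sorted(set(l1) - set(l2))
        only2 = sorted(set(l2) - set(l1))
        raise TreeComparisonError(
            f"{metric}: leaf sets differ (only in first: {only1}, only in second: {only2})"
        )
    if len(l1) < min_n:
        raise TreeComparisonError(
            f"{metric}: needs at least {min_n} taxa, got {len(l1)}"
        )
    labels = tuple(l1)
    if metric in _ROOTED_METRICS:
        t1 = _rooted_view(t1)
        t2 = _rooted_view(t2)
    return _TreeView(t1, labels), _TreeView(t2, labels)


def _rooted_view(tree: dendropy.Tree) -> dendropy.Tree:
    if tree.is_rooted:
        return tree
    return midpoint_root(tree)


# ---------------------------------------------------------------------------
# unrooted metrics
# ---------------------------------------------------------------------------

def rf_distance(t1, t2) -> MetricResult:
    """Robinson-Foulds: halved symmetric difference of nontrivial splits."""
    v1, v2 = _prepare(t1, t2, "rf", 4)
    s1, s2 = v1.splits(), v2.splits()
    raw = len(s1 ^ s2) / 2.0
    max_rf = v1.n - 3  # binary unrooted maximum
    return MetricResult("rf", raw, raw / max_rf if max_rf > 0 else None, v1.n)


def quartet_distance(t1, t2) -> MetricResult:
    """Number of 4-leaf subsets with differing induced quartet topology."""
    v1, v2 = _prepare(t1, t2, "quartet", 4)
    p1 = v1.path_matrix(topological=True)
    p2 = v2.path_matrix(topological=True)
    raw = 0
    for q in itertools.combinations(range(v1.n), 4):
        if _quartet_topology(p1, q) != _quartet_topology(p2, q):
            raw += 1
    return MetricResult("quartet", float(raw), raw / comb(v1.n, 4), v1.n)


def _quartet_topology(p: np.ndarray, q) -> int:
    """0: ab|cd, 1: ac|bd, 2: ad|bc, 3: star, for leaves q=(a,b,c,d)."""
    a, b, c, d = q
    sums = (p[a, b] + p[c, d], p[a, c] + p[b, d], p[a, d] + p[b, c])
    m = min(sums)
    winners = [i for i, s in enumerate(sums) if s == m]
    return winners[0] if len(winners) == 1 else 3


def path_difference(t1, t2) -> MetricResult:
    """L2 norm of the difference of topological leaf-leaf path matrices."""
    v1, v2 = _prepare(t1, t2, "path_difference", 3)
    p1 = v1.path_matrix(topological=True)
    p2 = v2.path_matrix(topological=True)
    iu = np.triu_indices(v1.n, k=1)
    return MetricResult(
        "path_difference", float(np.linalg.norm(p1[iu] - p2[iu])), None, v1.n
    )


def cophenetic_l2(t1, t2) -> MetricResult:
    """L2 norm of the difference of patristic (branch-length) matrices."""
    v1, v2 = _prepare(t1, t2, "cophenetic", 3)
    p1 = v1.path_matrix(topological=False)
    p2 = v2.path_matrix(topological=False)
    iu = np.triu_indices(v1.n, k=1)
    return MetricResult(
        "cophenetic", float(np.linalg.norm(p1[iu] - p2[iu])), None, v1.n
    )


def matching_pair(t1, t2) -> MetricResult:
    """Minimum-weight matching between nontrivial splits.

    The cost between two splits is the number of unordered leaf pairs they
    classify differently (together vs apart); an unmatched split costs its
    own pairs-together count.
    """
    v1, v2 = _prepare(t1, t2, "matching_pair", 4)
    s1, s2 = sorted(v1.splits()), sorted(v2.splits())
    full = v1.full

    def together(mask: int) -> int:
        k = mask.bit_count()
        return comb(k, 2) + comb(v1.n - k, 2)

    def cost(m1: int, m2: int) -> int:
        a = (m1 & m2).bit_count()
        b = (m1 & ~m2 & full).bit_count()
        c = (~m1 & m2 & full).bit_count()
        d = (~m1 & ~m2 & full).bit_count()
        t12 = comb(a, 2) + comb(b, 2) + comb(c, 2) + comb(d, 2)
        return together(m1) + together(m2) - 2 * t12

    raw = _padded_matching(s1, s2, cost, together)
    return MetricResult("matching_pair", float(raw), None, v1.n)


# ---------------------------------------------------------------------------
# rooted metrics
# ---------------------------------------------------------------------------

def triples_distance(t1, t2) -> MetricResult:
    """Number of leaf triples whose rooted triplet topology differs."""
    v1, v2 = _prepare(t1, t2, "triples", 3)
    _, lca1 = v1.depths()
    _, lca2 = v2.depths()
    raw = 0
    for tr in itertools.combinations(range(v1.n), 3):
        if _triple_topology(lca1, tr) != _triple_topology(lca2, tr):
            raw += 1
    return MetricResult("triples", float(raw), raw / comb(v1.n, 3), v1.n)


def _triple_topology(lca: np.ndarray, tr) -> int:
    """0: bc deepest (a is out), 1: ac deepest, 2: ab deepest, 3: star."""
    a, b, c = tr
    depths = (lca[b, c], lca[a, c], lca[a, b])
    m = max(depths)
    winners = [i for i, d in enumerate(depths) if d == m]
    return winners[0] if len(winners) == 1 else 3


def matching_cluster(t1, t2) -> MetricResult:
    """Minimum-weight matching between nontrivial rooted clusters; the cost
    is the symmetric-difference size of the two leaf sets, and an unmatched
    cluster is paired with the empty set (cost = its size)."""
    v1, v2 = _prepare(t1, t2, "matching_cluster", 3)
    c1, c2 = sorted(v1.clusters()), sorted(v2.clusters())

    def cost(m1: int, m2: int) -> int:
        return (m1 ^ m2).bit_count()

    def solo(m: int) -> int:
        return m.bit_count()

    raw = _padded_matching(c1, c2, cost, solo)
    return MetricResult("matching_cluster", float(raw), None, v1.n)


def nodal_splitted(t1, t2) -> MetricResult:
    """L2 norm over ordered leaf pairs (i, j) of the difference in edge
    counts from leaf i up to the LCA of i and j (splitted nodal distance)."""
    v1, v2 = _prepare(t1, t2, "nodal_splitted", 3)
    d1, lca1 = v1.depths()
    d2, lca2 = v2.depths()
    up1 = d1[:, None] - lca1
    up2 = d2[:, None] - lca2
    off = ~np.eye(v1.n, dtype=bool)
    return MetricResult(
        "nodal_splitted", float(np.linalg.norm(up1[off] - up2[off])), None, v1.n
    )


def mast_distance(t1, t2) -> MetricResult:
    """Leaves removed to reach the maximum agreement subtree: n - |MAST|.

    Exact dynamic program over rooted node pairs; multifurcating nodes are
    handled with a maximum-weight child matching (Hungarian algorithm).
    """
    v1, v2 = _prepare(t1, t2, "mast", 3)
    nodes1 = list(v1.tree.postorder_node_iter())
    nodes2 = list(v2.tree.postorder_node_iter())
    idx1 = {id(nd): i for i, nd in enumerate(nodes1)}
    idx2 = {id(nd): i for i, nd in enumerate(nodes2)}
    table = np.zeros((len(nodes1), len(nodes2)), dtype=np.int64)

    for i, u in enumerate(nodes1):
        mu = v1.mask[id(u)]
        for j, w in enumerate(nodes2):
            mw = v2.mask[id(w)]
            if u.is_leaf() or w.is_leaf():
                table[i, j] = 1 if (mu & mw) else 0
                continue
            best = 0
            for ch in u.child_nodes():
                best = max(best, table[idx1[id(ch)], j])
            for ch in w.child_nodes():
                best = max(best, table[i, idx2[id(ch)]])
            kids_u = [idx1[id(c)] for c in u.child_nodes()]
            kids_w = [idx2[id(c)] for c in w.child_nodes()]
            weights = table[np.ix_(kids_u, kids_w)]
            r, c = linear_sum_assignment(weights, maximize=True)
            best = max(best, int(weights[r, c].sum()))
            table[i, j] = best

    mast = int(table[-1, -1])
    return MetricResult("mast", float(v1.n - mast), (v1.n - mast) / v1.n, v1.n)


# ---------------------------------------------------------------------------

def _padded_matching(items1, items2, cost, solo) -> int:
    """Minimum-cost assignment between two item lists, padding the shorter
    side with 'absent' items whose pairing cost is ``solo(item)``."""
    n1, n2 = len(items1), len(items2)
    size = max(n1, n2)
    if size == 0:
        return 0
    mat = np.zeros((size, size))
    for i in range(size):
        for j in range(size):
            if i < n1 and j < n2:
                mat[i, j] = cost(items1[i], items2[j])
            elif i < n1:
                mat[i, j] = solo(items1[i])
            elif j < n2:
                mat[i, j] = solo(items2[j])
    r, c = linear_sum_assignment(mat)
    return int(round(mat[r, c].sum()))


_METRIC_FUNCS = {
    "triples": triples_distance,
    "rf": rf_distance,
    "matching_pair": matching_pair,
    "nodal_splitted": nodal_splitted,
    "matching_cluster": matching_cluster,
    "mast": mast_distance,
    "cophenetic": cophenetic_l2,
    "quartet": quartet_distance,
    "path_difference": path_difference,
}


def compare_all(t1: dendropy.Tree, t2: dendropy.Tree) -> list[MetricResult]:
    """All nine metrics for a tree pair, in the stable order of
    ``METRIC_NAMES``. Rooted metrics midpoint-root unrooted inputs."""
    return [_METRIC_FUNCS[name](t1, t2) for name in METRIC_NAMES]
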