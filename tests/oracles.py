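"""Brute-force reference implementations used only in tests.

These deliberately take different algorithmic routes from the package:
nested-tuple tree restriction and canonical forms instead of bitmask
dynamic programming, path-disjointness instead of four-point sums,
exhaustive permutation search instead of the Hungarian algorithm.
"""

from __future__ import annotations

import itertools
from math import comb


def to_nested(tree):
    """Dendropy tree -> nested tuple structure (leaves are label strings)."""

    def conv(node):
        if node.is_leaf():
            return node.taxon.label
        return tuple(conv(c) for c in node.child_nodes())

    return conv(tree.seed_node)


def leaves_of(nested):
    if isinstance(nested, str):
        return {nested}
    out = set()
    for c in nested:
        out |= leaves_of(c)
    return out


def restrict(nested, keep):
    """Induced rooted topology on ``keep`` with unary nodes suppressed."""
    if isinstance(nested, str):
        return nested if nested in keep else None
    kids = [restrict(c, keep) for c in nested]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def canon(nested):
    """Canonical form invariant to child order (label-preserving isomorphism)."""
    if isinstance(nested, str):
        return nested
    return tuple(sorted((canon(c) for c in nested), key=repr))


# ---------------------------------------------------------------------------
# per-metric oracles
# ---------------------------------------------------------------------------

def splits_oracle(tree):
    """Nontrivial splits of the unrooted view as frozensets of labels."""
    nested = to_nested(tree)
    all_leaves = frozenset(leaves_of(nested))
    out = set()

    def walk(node):
        if isinstance(node, str):
            return frozenset([node])
        below = frozenset()
        for c in node:
            sub = walk(c)
            if 2 <= len(sub) <= len(all_leaves) - 2:
                side = sub if min(all_leaves) not in sub else all_leaves - sub
                out.add(side)
            below |= sub
        return below

    walk(nested)
    return out


def rf_oracle(t1, t2):
    s1, s2 = splits_oracle(t1), splits_oracle(t2)
    return len(s1 ^ s2) / 2.0


def _ancestor_paths(nested):
    """label -> tuple of nested nodes from root down to the leaf."""
    paths = {}

    def walk(node, trail):
        trail = trail + (node,)
        if isinstance(node, str):
            paths[node] = trail
            return
        for c in node:
            walk(c, trail)

    walk(nested, ())
    return paths


def triple_oracle_topology(nested_paths, a, b, c):
    """Which pair forms the cherry, via MRCA depths from ancestor chains."""

    def mrca_depth(x, y):
        px, py = nested_paths[x], nested_paths[y]
        d = 0
        while d < min(len(px), len(py)) and px[d] is py[d]:
            d += 1
        return d - 1

    depths = {("b", "c"): mrca_depth(b, c), ("a", "c"): mrca_depth(a, c),
              ("a", "b"): mrca_depth(a, b)}
    mx = max(depths.values())
    winners = [k for k, v in depths.items() if v == mx]
    return winners[0] if len(winners) == 1 else "star"


def triples_oracle(t1, t2):
    n1, n2 = to_nested(t1), to_nested(t2)
    p1, p2 = _ancestor_paths(n1), _ancestor_paths(n2)
    labels = sorted(leaves_of(n1))
    count = 0
    for a, b, c in itertools.combinations(labels, 3):
        if triple_oracle_topology(p1, a, b, c) != triple_oracle_topology(p2, a, b, c):
            count += 1
    return float(count)


def quartet_oracle_topology(nested_paths, w, x, y, z):
    """Quartet topology by path disjointness: wx|yz iff path(w,x) and
    path(y,z) share no node of the (rooted) tree."""

    def path_nodes(a, b):
        pa, pb = nested_paths[a], nested_paths[b]
        d = 0
        while d < min(len(pa), len(pb)) and pa[d] is pb[d]:
            d += 1
        # nodes strictly below the mrca on both sides, plus the mrca
        return {id(nd) for nd in pa[d - 1:]} | {id(nd) for nd in pb[d - 1:]}

    for pair, rest, tag in (
        ((w, x), (y, z), "wx|yz"),
        ((w, y), (x, z), "wy|xz"),
        ((w, z), (x, y), "wz|xy"),
    ):
        if not (path_nodes(*pair) & path_nodes(*rest)):
            return tag
    return "star"


def quartet_oracle(t1, t2):
    n1, n2 = to_nested(t1), to_nested(t2)
    p1, p2 = _ancestor_paths(n1), _ancestor_paths(n2)
    labels = sorted(leaves_of(n1))
    count = 0
    for q in itertools.combinations(labels, 4):
        if quartet_oracle_topology(p1, *q) != quartet_oracle_topology(p2, *q):
            count += 1
    return float(count)


def mast_oracle(t1, t2):
    """n - size of the largest leaf subset with isomorphic restrictions."""
    n1, n2 = to_nested(t1), to_nested(t2)
    labels = sorted(leaves_of(n1))
    n = len(labels)
    for size in range(n, 0, -1):
        for subset in itertools.combinations(labels, size):
            keep = set(subset)
            if canon(restrict(n1, keep)) == canon(restrict(n2, keep)):
                return float(n - size)
    return float(n)


def exhaustive_matching(items1, items2, cost, solo):
    """Minimum total cost over all pairings, padding with absent items."""
    size = max(len(items1), len(items2))
    a = list(items1) + [None] * (size - len(items1))
    b = list(items2) + [None] * (size - len(items2))
    best = None
    for perm in itertools.permutations(range(size)):
        total = 0
        for i, j in enumerate(perm):
            if a[i] is None and b[j] is None:
                continue
            if a[i] is None:
                total += solo(b[j])
            elif b[j] is None:
                total += solo(a[i])
            else:
                total += cost(a[i], b[j])
        if best is None or total < best:
            best = total
    return float(best or 0)


def matching_cluster_oracle(t1, t2):
    def clusters(tree):
        nested = to_nested(tree)
        n = len(leaves_of(nested))
        out = []

        def walk(node):
            if isinstance(node, str):
                return frozenset([node])
            below = frozenset().union(*(walk(c) for c in node))
            if 2 <= len(below) <= n - 1:
                out.append(below)
            return below

        walk(nested)
        return out

    cost = lambda c1, c2: len(c1 ^ c2)
    solo = lambda c: len(c)
    return exhaustive_matching(clusters(t1), clusters(t2), cost, solo)


def matching_pair_oracle(t1, t2):
    labels = sorted(leaves_of(to_nested(t1)))
    pairs = list(itertools.combinations(labels, 2))

    def together(split):
        return {p for p in pairs if (p[0] in split) == (p[1] in split)}

    def cost(s1, s2):
        return len(together(s1) ^ together(s2))

    def solo(s):
        return len(together(s))

    return exhaustive_matching(
        sorted(splits_oracle(t1), key=sorted),
        sorted(splits_oracle(t2), key=sorted),
        cost,
        solo,
    )


def nodal_splitted_oracle(t1, t2):
    """L2 over ordered pairs of (depth of i minus depth of mrca(i, j))."""

    def upvec(tree):
        paths = _ancestor_paths(to_nested(tree))
        labels = sorted(paths)
        vec = []
        for i in labels:
            for j in labels:
                if i == j:
                    continue
                pi, pj = paths[i], paths[j]
                d = 0
                while d < min(len(pi), len(pj)) and pi[d] is pj[d]:
                    d += 1
                # depth of leaf i is len(pi) - 1, mrca depth is d - 1
                vec.append((len(pi) - 1) - (d - 1))
        return vec

    v1, v2 = upvec(t1), upvec(t2)
    return float(sum((x - y) ** 2 for x, y in zip(v1, v2)) ** 0.5)
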