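"""Unrooted-topology enumeration and additive distances (test oracles)."""

import heapq


def all_unrooted_topologies(labels):
    """Every unrooted binary topology over ``labels``, as edge lists.

    Built by stepwise leaf insertion: each topology over n leaves arises
    exactly once from inserting the n-th leaf into one edge of a topology
    over n − 1 leaves.
    """
    def insert(tree_edges, leaf):
        for i in range(len(tree_edges)):
            mid = ("x", leaf, i)
            yield tree_edges[:i] + tree_edges[i + 1 :] + [
                (tree_edges[i][0], mid),
                (mid, tree_edges[i][1]),
                (mid, leaf),
            ]

    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    trees = [[(labels[0], ("i", 0)), (labels[1], ("i", 0)),
              (labels[2], ("i", 0))]]
    for leaf in labels[3:]:
        trees = [t2 for t in trees for t2 in insert(t, leaf)]
    return trees


def edges_to_distances(edges, labels, lengths):
    """Additive leaf-to-leaf distance matrix (Dijkstra over the tree)."""
    import numpy as np

    adj = {}
    for (a, b), w in zip(edges, lengths):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    n = len(labels)
    m = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        heap = [(0.0, 0, src)]
        tiebreak = 1
        while heap:
            d, _, node = heapq.heappop(heap)
            if d > dist.get(node, float("inf")):
                continue
            for nb, w in adj[node]:
                nd = d + w
                if nd < dist.get(nb, float("inf")):
                    dist[nb] = nd
                    heapq.heappush(heap, (nd, tiebreak, nb))
                    tiebreak += 1
        for j, dst in enumerate(labels):
            m[i, j] = dist[dst]
    return m


def splits_from_edges(edges, labels):
    """Non-trivial bipartitions of a topology, canonicalized like
    FamilyTree.splits()."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    ref = labels[0]
    out = set()
    for a, b in edges:
        # leaves reachable from a without crossing (a, b)
        seen = {a}
        stack = [a]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb == b and node == a:
                    continue
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(x for x in seen if x in labels)
        if ref in side:
            side = frozenset(labels) - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out
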