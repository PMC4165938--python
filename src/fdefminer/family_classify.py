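"""Family classification of mature defensins.

Pairwise global-alignment p-distances, neighbor-joining tree construction
with deterministic tie-breaking, column-bootstrap support over a star
progressive alignment, and anchor-based family assignment (fDEF1–8, with a
"new"-family call for well-supported anchor-free clades of low identity).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .alignment import needleman_wunsch
from .errors import ValidationError


def pairwise_identity(a: str, b: str) -> float:
    """Global (Needleman–Wunsch, affine gaps) identity: matches / columns."""
    if not a or not b:
        raise ValidationError("empty peptide")
    return needleman_wunsch(a, b).identity


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if m.min() < -1e-12:
            raise ValidationError("negative distances")
        self.matrix = m

    @classmethod
    def from_peptides(cls, peptides: list[tuple[str, str]],
                      correction: str = "p") -> "DistanceMatrix":
        """p-distances (1 − identity) from all-pairs global alignment.

        ``correction="poisson"`` applies −ln(1 − p) to each distance.
        """
        labels = [n for n, _ in peptides]
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = 1.0 - pairwise_identity(peptides[i][1], peptides[j][1])
                if correction == "poisson":
                    p = -math.log(max(1.0 - p, 1e-9))
                m[i, j] = m[j, i] = p
        return cls(labels, m)


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, with_support: bool = True) -> str:
        return self._newick(with_support, root=True) + ";"

    def _newick(self, with_support: bool, root: bool = False) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None and not root:
            label = f"{self.support:.0f}"
        tail = "" if root else f":{self.length:.6g}"
        return f"({inner}){label}{tail}"


@dataclass
class FamilyTree:
    """Unrooted NJ tree (trifurcating root) with bootstrap support."""

    root: TreeNode
    anchors: dict[str, str] = field(default_factory=dict)  # leaf -> family

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side *not*
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def clades_with_support(self, min_support: float = 50.0):
        """(leaf set, support) for internal edges meeting the threshold;
        sides reported as seen from each internal node."""
        all_leaves = self.leaf_names()
        out = []
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            if node.support is not None and node.support >= min_support:
                side = node.leaf_names()
                out.append((side, node.support))
                out.append((all_leaves - side, node.support))
        return out

    def to_newick(self, with_support: bool = True) -> str:
        return self.root.to_newick(with_support)


def neighbor_joining(dm: DistanceMatrix) -> FamilyTree:
    """Standard NJ agglomeration.

    Q-matrix minimization; ties resolved to the lexicographically smallest
    label pair (internal nodes keyed by their smallest descendant leaf).
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes = [TreeNode(name=l) for l in dm.labels]
    keys = list(dm.labels)  # tie-break key: smallest descendant leaf label

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        i, j = min(
            (tuple(sorted((keys[a], keys[b]))), (min(a, b), max(a, b)))
            for a, b in ties
        )[1]
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0
        a, b = nodes[i], nodes[j]
        a.length, b.length = float(li), float(lj)
        parent = TreeNode(children=[a, b])
        newd = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newd[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    d12, d13, d23 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        max(0.0, 0.5 * (d12 + d13 - d23)),
        max(0.0, 0.5 * (d12 + d23 - d13)),
        max(0.0, 0.5 * (d13 + d23 - d12)),
    ]
    for node, length in zip(nodes, lengths):
        node.length = float(length)
    order = sorted(range(3), key=lambda k: keys[k])
    root = TreeNode(children=[nodes[k] for k in order])
    return FamilyTree(root=root)


# -- alignment & bootstrap --------------------------------------------------


def star_alignment(peptides: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Progressive multiple alignment against the longest member as guide.

    Each sequence is aligned to the guide by global NW; per-guide-position
    insertions are padded to their maximum across members.
    """
    if len(peptides) < 2:
        return list(peptides)
    guide_idx = max(range(len(peptides)),
                    key=lambda k: (len(peptides[k][1]), peptides[k][0]))
    guide = peptides[guide_idx][1]
    G = len(guide)

    def chunks_of(ga: str, gb: str) -> list[str]:
        """chunk[0]: member residues before guide column 1; chunk[p] (p>=1):
        member char in guide column p plus any insertion after it."""
        chunks = [""] * (G + 1)
        p = 0
        for x, y in zip(ga, gb):
            if x != "-":
                p += 1
                chunks[p] = y
            else:
                chunks[p] += y
        return chunks

    member_chunks: dict[int, list[str]] = {
        guide_idx: [""] + list(guide)
    }
    for k, (_, seq) in enumerate(peptides):
        if k == guide_idx:
            continue
        aln = needleman_wunsch(guide, seq)
        member_chunks[k] = chunks_of(aln.aligned_a, aln.aligned_b)

    widths = [
        max(len(member_chunks[k][p]) for k in member_chunks)
        for p in range(G + 1)
    ]
    aligned = []
    for k in range(len(peptides)):
        chunks = member_chunks[k]
        parts = [chunks[0].rjust(widths[0], "-")]
        parts += [chunks[p].ljust(widths[p], "-") for p in range(1, G + 1)]
        aligned.append((peptides[k][0], "".join(parts)))
    if len({len(s) for _, s in aligned}) != 1:
        raise ValidationError("star alignment width mismatch")
    return aligned


def _msa_distances(rows: np.ndarray) -> np.ndarray:
    """p-distance matrix from an encoded MSA (gap = 0)."""
    n = rows.shape[0]
    eq = (rows[:, None, :] == rows[None, :, :]) & (rows[:, None, :] != 0)
    d = 1.0 - eq.sum(axis=2) / rows.shape[1]
    np.fill_diagonal(d, 0.0)
    return d


def bootstrap_support(alignment: list[tuple[str, str]], n_reps: int = 500,
                      seed: int = 0,
                      tree: Optional[FamilyTree] = None) -> FamilyTree:
    """Column bootstrap: NJ per resampled alignment, edge frequency in %.

    Returns the (given or freshly built) tree with ``support`` set on its
    internal nodes.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    labels = [n for n, _ in alignment]
    width = len(alignment[0][1])
    code = {c: k for k, c in enumerate("-ACDEFGHIKLMNPQRSTVWYBZX*", start=0)}
    rows = np.array(
        [[code.get(c, 0) for c in s] for _, s in alignment], dtype=np.int8
    )
    if tree is None:
        tree = neighbor_joining(DistanceMatrix(labels, _msa_distances(rows)))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep = neighbor_joining(
            DistanceMatrix(labels, _msa_distances(rows[:, cols]))
        )
        for split in rep.splits():
            counts[split] = counts.get(split, 0) + 1
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        node.support = 100.0 * counts.get(side, 0) / n_reps
    return tree


def assign_family(tree: FamilyTree, anchors: dict[str, str], query: str,
                  identity_to_anchor: Callable[[str, str], float],
                  min_support: float = 50.0,
                  new_identity_max: float = 0.30) -> str:
    """Family of ``query`` from its smallest well-supported anchored clade.

    ``identity_to_anchor(query, anchor_leaf)`` supplies pairwise identities.
    A query whose best identity to every anchor is below
    ``new_identity_max`` and which sits in a ≥``min_support`` clade free of
    anchors is labelled ``"new"``; with no informative supported clade the
    nearest anchor's family is used.
    """
    if query not in tree.leaf_names():
        raise ValidationError(f"query {query!r} not in tree")
    best_ident = {a: identity_to_anchor(query, a) for a in anchors}
    clades = [c for c in tree.clades_with_support(min_support)
              if query in c[0] and len(c[0]) < len(tree.leaf_names())]
    clades.sort(key=lambda c: len(c[0]))
    if max(best_ident.values(), default=0.0) < new_identity_max:
        for side, _ in clades:
            if len(side) >= 2 and not (side & set(anchors)):
                return "new"
    for side, _ in clades:
        in_clade = side & set(anchors)
        if in_clade:
            # majority family of the anchors in the clade; ties resolved by
            # the highest pairwise identity to the query
            counts: dict[str, int] = {}
            best_by_family: dict[str, float] = {}
            for a in in_clade:
                f = anchors[a]
                counts[f] = counts.get(f, 0) + 1
                best_by_family[f] = max(best_by_family.get(f, 0.0),
                                        best_ident[a])
            return max(sorted(counts),
                       key=lambda f: (counts[f], best_by_family[f]))
    if best_ident:
        return anchors[max(sorted(best_ident), key=lambda a: best_ident[a])]
    return "unassigned"
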