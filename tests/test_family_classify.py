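import itertools
import random

import numpy as np
import pytest

from fdefminer.errors import ValidationError
from fdefminer.family_classify import (
    DistanceMatrix,
    TreeNode,
    assign_family,
    bootstrap_support,
    neighbor_joining,
    pairwise_identity,
    star_alignment,
)
from fdefminer.synthetic_data import generate_mature


from tree_utils import all_unrooted_topologies, edges_to_distances, splits_from_edges


class TestDistanceMatrix:
    def test_validates_symmetry(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_from_peptides_p_distance(self):
        dm = DistanceMatrix.from_peptides([("a", "ACDE"), ("b", "ACDF")])
        assert dm.matrix[0, 1] == pytest.approx(0.25)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], m))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxon_topology(self):
        # ((a,b),(c,d)) with internal edge 3
        labels = ["a", "b", "c", "d"]
        m = np.array([
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 5],
            [10, 11, 5, 0],
        ], float)
        tree = neighbor_joining(DistanceMatrix(labels, m))
        assert frozenset({"c", "d"}) in tree.splits() or \
            frozenset({"b", "a"}) in tree.splits()

    def test_path_lengths_reproduce_additive_input(self):
        rng = random.Random(0)
        labels = list("abcde")
        # random additive matrix from a fixed 5-leaf tree
        topo = all_unrooted_topologies(labels)[3]
        lengths = [0.5 + rng.random() for _ in topo]
        m = edges_to_distances(topo, labels, lengths)
        tree = neighbor_joining(DistanceMatrix(labels, m))

        def leaf_dists(node, acc, out):
            if node.is_leaf:
                out[node.name] = acc + node.length
                return
            for c in node.children:
                leaf_dists(c, acc + (node.length if node.length else 0), out)

        # pairwise path lengths via recursive traversal
        def tree_dist(x, y):
            def paths(node, target, acc):
                if node.is_leaf:
                    return acc + node.length if node.name == target else None
                for c in node.children:
                    r = paths(c, target, acc + node.length)
                    if r is not None:
                        return r
                return None

            return paths(tree.root, x, 0) + paths(tree.root, y, 0) - \
                2 * _shared(tree.root, x, y)

        def _shared(root, x, y):
            # length of the shared path from root toward both leaves
            node, acc = root, 0.0
            while True:
                nxt = [c for c in node.children
                       if x in c.leaf_names() and y in c.leaf_names()]
                if not nxt:
                    return acc
                node = nxt[0]
                acc += node.length

        for x, y in itertools.combinations(labels, 2):
            i, j = labels.index(x), labels.index(y)
            assert tree_dist(x, y) == pytest.approx(m[i, j], abs=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_recovers_topology_exhaustively(self, n):
        labels = [f"t{i}" for i in range(n)]
        for k, topo in enumerate(all_unrooted_topologies(labels)):
            lengths = [1.0 + 0.1 * ((k + i) % 7) for i in range(len(topo))]
            m = edges_to_distances(topo, labels, lengths)
            tree = neighbor_joining(DistanceMatrix(labels, m))
            assert tree.splits() == splits_from_edges(topo, labels), k

    def test_needs_three_taxa(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_matches_skbio_topology(self):
        """Independent cross-check against scikit-bio's NJ."""
        import skbio

        rng = random.Random(5)
        labels = [f"s{i}" for i in range(7)]
        peps = [(l, generate_mature(rng.randrange(2**31),
                                    "plectasin", p_sub=0.4)) for l in labels]
        dm = DistanceMatrix.from_peptides(peps)
        ours = neighbor_joining(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=labels))
        ref = labels[0]
        sk_splits = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(labels) - side
            if 2 <= len(side) <= len(labels) - 2:
                sk_splits.add(side)
        assert ours.splits() == sk_splits


class TestStarAlignmentAndBootstrap:
    def test_alignment_columns_consistent(self):
        peps = [("a", "GFGCNGPWDEDDMQC"), ("b", "GFGCNGPWDC"),
                ("c", "GFGCGPWDEDDMQC")]
        msa = star_alignment(peps)
        widths = {len(s) for _, s in msa}
        assert len(widths) == 1
        for name, gapped in msa:
            orig = dict(peps)[name]
            assert gapped.replace("-", "") == orig

    def test_identical_clades_get_full_support(self):
        peps = [("a1", "GFGCNGPWDEDDMQCHNHCKSIKGYKGGYCAKGGFVCKCY"),
                ("a2", "GFGCNGPWDEDDMQCHNHCKSIKGYKGGYCAKGGFVCKCY"),
                ("b1", "WDECTEGDGEEDQFNECNIKCSDKDLDQSECRFHGECGCRN"),
                ("b2", "WDECTEGDGEEDQFNECNIKCSDKDLDQSECRFHGECGCRN")]
        msa = star_alignment(peps)
        tree = bootstrap_support(msa, n_reps=100, seed=1)
        split = frozenset({"b1", "b2"})
        supports = {
            node.leaf_names(): node.support
            for node in tree.root.walk() if not node.is_leaf
        }
        found = [s for side, s in supports.items()
                 if side in (split, frozenset({"a1", "a2"}))]
        assert found and all(s == 100.0 for s in found)

    def test_bootstrap_deterministic_given_seed(self):
        rng = random.Random(2)
        peps = [(f"p{i}", generate_mature(rng.randrange(2**31), "plectasin",
                                          p_sub=0.35)) for i in range(6)]
        msa = star_alignment(peps)
        t1 = bootstrap_support(msa, n_reps=50, seed=9)
        t2 = bootstrap_support(star_alignment(peps), n_reps=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_divergent_families_strongly_supported(self):
        rng = random.Random(3)
        peps = [(f"a{i}", generate_mature(rng.randrange(2**31), "plectasin",
                                          p_sub=0.15)) for i in range(4)]
        peps += [(f"b{i}", generate_mature(rng.randrange(2**31),
                                           "anchor-fDEF6", p_sub=0.15))
                 for i in range(4)]
        tree = bootstrap_support(star_alignment(peps), n_reps=100, seed=4)
        split = frozenset(n for n, _ in peps if n.startswith("b"))
        support = {
            (frozenset(tree.leaf_names()) - node.leaf_names()
             if "a0" in node.leaf_names() else node.leaf_names()): node.support
            for node in tree.root.walk()
            if not node.is_leaf and node is not tree.root
        }.get(split)
        assert support is not None and support >= 90

    def test_rejects_zero_replicates(self):
        with pytest.raises(ValidationError):
            bootstrap_support([("a", "AC"), ("b", "AC"), ("c", "AC")],
                              n_reps=0)


class TestAssignFamily:
    def _setup(self, queries, p_sub=0.25, seed=11):
        from fdefminer.synthetic_data import FAMILY_TEMPLATES

        anchors = {}
        peps = []
        for name, (seq, fam) in sorted(FAMILY_TEMPLATES.items()):
            anchors[name] = fam
            peps.append((name, seq))
        peps += queries
        tree = bootstrap_support(star_alignment(peps), n_reps=100, seed=seed)
        seq_of = dict(peps)

        def ident(q, a):
            return pairwise_identity(seq_of[q], seq_of[a])

        return tree, anchors, ident

    def test_query_identical_to_plectasin_is_fdef1(self):
        from fdefminer.synthetic_data import FAMILY_TEMPLATES

        q = FAMILY_TEMPLATES["plectasin"][0]
        tree, anchors, ident = self._setup([("q", q)])
        assert assign_family(tree, anchors, "q", ident) == "fDEF1"

    def test_divergent_clade_is_new_family(self):
        # five similar peptides unlike any anchor
        base = "GWINEWTKDSKTWLNDLPHIDPNEWARTWSHDMNLWHKENPWLTK"
        rng = random.Random(6)
        queries = []
        for i in range(5):
            s = list(base)
            for _ in range(3):
                p = rng.randrange(len(s))
                s[p] = rng.choice("GWINDETKSH")
            queries.append((f"q{i}", "".join(s)))
        tree, anchors, ident = self._setup(queries)
        calls = {q: assign_family(tree, anchors, q, ident)
                 for q, _ in queries}
        assert all(v == "new" for v in calls.values()), calls

    def test_missing_query_rejected(self):
        tree, anchors, ident = self._setup([("q", "GFGCNGPWDEDDMQCHNHCKSIKGYKGGYCAKGGFVCKCY")])
        with pytest.raises(ValidationError):
            assign_family(tree, anchors, "zz", ident)


def test_newick_output_parses_with_skbio():
    import io

    import skbio

    m = np.array([[0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]],
                 float)
    tree = neighbor_joining(DistanceMatrix(list("abcd"), m))
    parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
    assert {t.name for t in parsed.tips()} == set("abcd")
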