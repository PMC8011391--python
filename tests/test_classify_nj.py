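"""Neighbour-Joining: tree reconstruction and smallest-subtree classification."""

import numpy as np
import pytest

from speciesid.classify import AMBIGUOUS, build_nj, classify_nj
from speciesid.classify.njtree import NJTree, Node
from speciesid.distance import DistanceMatrix
from speciesid.genotype_data import LabelSet
from speciesid.distance import divergent_sites


def random_additive_matrix(n_leaves, rng):
    """Distances generated from a random binary tree with positive branches."""
    # build a random topology by sequential leaf insertion
    nodes = [Node(name=f"L{i}") for i in range(n_leaves)]
    edges = {}  # adjacency: node -> list of (node, length)

    def connect(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    connect(nodes[0], nodes[1], float(rng.uniform(0.5, 2)))
    internal_count = 0
    for leaf in nodes[2:]:
        # pick a random existing edge and subdivide it
        all_edges = [(a, b, w) for a in edges for b, w in edges[a] if id(a) < id(b)]
        a, b, w = all_edges[rng.integers(0, len(all_edges))]
        mid = Node(name=None)
        internal_count += 1
        edges[a] = [(x, y) for x, y in edges[a] if x is not b]
        edges[b] = [(x, y) for x, y in edges[b] if x is not a]
        split = float(rng.uniform(0.2, 0.8)) * w
        connect(a, mid, split)
        connect(b, mid, w - split)
        connect(mid, leaf, float(rng.uniform(0.5, 2)))
    # leaf-to-leaf path lengths
    d = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(nodes):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(nodes):
            d[i, j] = dist[dst]
    np.fill_diagonal(d, 0.0)
    return [n.name for n in nodes], d


class TestBuildNJ:
    def test_four_taxon_split_recovered(self):
        """The {A,B}|{C,D} split of an additive 4x4 matrix must appear."""
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float
        )
        tree = build_nj(DistanceMatrix(list("ABCD"), d))
        # four-point check: path lengths reproduce the input exactly
        names, dd = tree.leaf_distances()
        order = [names.index(x) for x in "ABCD"]
        assert np.allclose(dd[np.ix_(order, order)], d)
        # the A,B pair must form a cherry on one side of the hub
        cherries = [
            sorted(leaf.name for leaf in child.leaves())
            for child in tree.root.children
            if not child.is_leaf
        ]
        assert ["A", "B"] in cherries or ["C", "D"] in cherries

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], dtype=float)
        tree = build_nj(DistanceMatrix(list("XYZ"), d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"X": 2.0, "Y": 1.0, "Z": 3.0}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_additivity_oracle(self, seed, n_leaves):
        """NJ on an additive matrix reproduces the input path lengths."""
        rng = np.random.default_rng(seed)
        names, d = random_additive_matrix(n_leaves, rng)
        tree = build_nj(DistanceMatrix(names, d))
        out_names, dd = tree.leaf_distances()
        order = [out_names.index(x) for x in names]
        assert np.allclose(dd[np.ix_(order, order)], d, atol=1e-8)

    def test_requires_three(self):
        with pytest.raises(ValueError):
            build_nj(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_negative_branches_recorded(self):
        # strongly non-additive matrix forces a negative branch estimate
        d = np.array(
            [[0, 1, 8, 8], [1, 0, 1, 8], [8, 1, 0, 1], [8, 8, 1, 0]], dtype=float
        )
        tree = build_nj(DistanceMatrix(list("ABCD"), d))
        for desc, orig in tree.diagnostics["negative_branches"]:
            assert orig < 0
        # all realised lengths clamped to >= 0
        def lengths(node):
            for c in node.children:
                yield c.length
                yield from lengths(c)
        assert all(x >= 0 for x in lengths(tree.root))


def ladder_tree():
    """Hand-built tree: q's clade ladder is (q,b1,c1) then +c2, far D cluster."""
    p1 = Node()
    for nm in ("q", "b1", "c1"):
        p1.add(Node(name=nm), 1.0)
    p2 = Node()
    p2.add(p1, 1.0)
    p2.add(Node(name="c2"), 1.0)
    hub = Node()
    hub.add(p2, 10.0)
    cluster = Node()
    cluster.add(Node(name="d1"), 1.0)
    cluster.add(Node(name="d2"), 1.0)
    hub.add(cluster, 1.0)
    hub.add(Node(name="d3"), 1.5)
    return NJTree(hub)


class TestClassifyNJ:
    def test_sibling_clade_majority(self):
        p1 = Node()
        for nm in ("q", "b1", "b2"):
            p1.add(Node(name=nm), 1.0)
        hub = Node()
        hub.add(p1, 10.0)
        hub.add(Node(name="d1"), 1.0)
        hub.add(Node(name="d2"), 1.5)
        labels = LabelSet({"q": "A", "b1": "B", "b2": "B", "d1": "D", "d2": "D"})
        preds = {p.accession_id: p for p in classify_nj(NJTree(hub), labels)}
        assert preds["q"].call == "B"
        assert preds["q"].support["level"] == 1

    def test_escalation_to_second_subtree(self):
        labels = LabelSet(
            {"q": "A", "b1": "B", "c1": "C", "c2": "C", "d1": "D", "d2": "D", "d3": "D"}
        )
        preds = {p.accession_id: p for p in classify_nj(ladder_tree(), labels)}
        # level 1 = {b1, c1}: B 1 vs C 1, no majority; level 2 adds c2 -> C
        assert preds["q"].call == "C"
        assert preds["q"].support["level"] == 2

    def test_ambiguous_after_two_levels(self):
        labels = LabelSet(
            {"q": "A", "b1": "B", "c1": "C", "c2": "B", "d1": "D", "d2": "D", "d3": "D"}
        )
        preds = {p.accession_id: p for p in classify_nj(ladder_tree(), labels)}
        # level 1 B:1 C:1; level 2 B:2 C:1 of 3 -> not > 50% ... B IS majority
        assert preds["q"].call == "B"

    def test_truly_ambiguous(self):
        # make level 2 a 2-2 split
        p1 = Node()
        for nm in ("q", "b1", "c1"):
            p1.add(Node(name=nm), 1.0)
        p2 = Node()
        p2.add(p1, 1.0)
        p2.add(Node(name="b2"), 1.0)
        p2.add(Node(name="c2"), 1.0)
        hub = Node()
        hub.add(p2, 10.0)
        hub.add(Node(name="d1"), 1.0)
        hub.add(Node(name="d2"), 1.5)
        labels = LabelSet(
            {"q": "A", "b1": "B", "c1": "C", "b2": "B", "c2": "C", "d1": "D", "d2": "D"}
        )
        preds = {p.accession_id: p for p in classify_nj(NJTree(hub), labels)}
        assert preds["q"].call == AMBIGUOUS

    def test_order_invariance(self, separated_collection):
        """Same calls regardless of accession input order."""
        gm, labels, _ = separated_collection
        preds1 = {
            p.accession_id: p.call
            for p in classify_nj(build_nj(divergent_sites(gm)), labels)
        }
        rng = np.random.default_rng(5)
        perm = rng.permutation(gm.n_accessions)
        gm2 = gm.take_accessions(perm)
        preds2 = {
            p.accession_id: p.call
            for p in classify_nj(build_nj(divergent_sites(gm2)), labels)
        }
        assert preds1 == preds2

    def test_newick_roundtrip_parses(self, tmp_path):
        tree = ladder_tree()
        path = tmp_path / "t.nwk"
        tree.write_newick(str(path))
        import dendropy

        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(tree.leaf_names)
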