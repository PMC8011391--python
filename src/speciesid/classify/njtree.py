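"""Neighbour-Joining tree construction and smallest-subtree classification.

The Saitou–Nei agglomeration is implemented directly (Q-matrix minimisation
with the standard branch-length formulas) so its behaviour — tie-breaking,
negative-branch clamping — is fully specified. Classification follows the
smallest-subtree majority rule used in DNA-barcoding comparisons: a query is
assigned the strict-majority species of the smallest clade properly
containing it; failing that, of the next enclosing clade; failing both, the
call is ambiguous. Because clades require a root and NJ trees are unrooted,
the tree is deterministically midpoint-rooted first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

from speciesid.classify.base import AMBIGUOUS, Prediction, majority
from speciesid.distance import DistanceMatrix
from speciesid.genotype_data import LabelSet


class Node:
    """Tree node; leaves carry a name, edges carry the length to the parent."""

    __slots__ = ("name", "children", "parent", "length", "orig_length")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length          # clamped, >= 0
        self.orig_length = length     # pre-clamp value, for diagnostics

    def add(self, child: "Node", length: float) -> None:
        child.parent = self
        child.length = max(0.0, length)
        child.orig_length = length
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def newick(self) -> str:
        return f"{self._newick_part()};"

    def _newick_part(self) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            body = "(" + ",".join(c._newick_part() for c in self.children) + ")"
        if self.length is not None:
            body += f":{self.length:.10g}"
        return body


@dataclass
class NJTree:
    """Unrooted NJ tree over accessions, represented via a degree-3 hub node.

    ``diagnostics["negative_branches"]`` lists (description, original length)
    for branches clamped to zero.
    """

    root: Node
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def newick(self) -> str:
        return self.root.newick()

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    # -- geometry -----------------------------------------------------------

    def _adjacency(self) -> dict[Node, list[tuple[Node, float]]]:
        adj: dict[Node, list[tuple[Node, float]]] = {}

        def walk(node: Node) -> None:
            adj.setdefault(node, [])
            for c in node.children:
                adj.setdefault(c, [])
                adj[node].append((c, c.length or 0.0))
                adj[c].append((node, c.length or 0.0))
                walk(c)

        walk(self.root)
        return adj

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """All pairwise leaf path lengths (clamped branch lengths)."""
        adj = self._adjacency()
        leaves = sorted((n for n in adj if n.is_leaf), key=lambda n: n.name)
        names = [n.name for n in leaves]
        index = {n: i for i, n in enumerate(leaves)}
        k = len(leaves)
        d = np.zeros((k, k))
        for src in leaves:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            i = index[src]
            for leaf, j in index.items():
                d[i, j] = dist[leaf]
        return names, d

    def midpoint_rooted(self) -> Node:
        """Root at the midpoint of the longest leaf-to-leaf path.

        Deterministic: among paths tied for longest, the lexicographically
        smallest (name-sorted) leaf pair is used. Returns a new rooted tree
        (degree-2 root); the unrooted tree is left untouched.
        """
        adj = self._adjacency()
        names, d = self.leaf_distances()
        leaves = sorted((n for n in adj if n.is_leaf), key=lambda n: n.name)
        k = len(leaves)
        best = (-1.0, None, None)
        for i in range(k):
            for j in range(i + 1, k):
                if d[i, j] > best[0] + 1e-12:
                    best = (d[i, j], leaves[i], leaves[j])
        total, u, v = best
        if u is None:
            raise ValueError("tree has fewer than 2 leaves")
        path = _path_between(adj, u, v)
        half = total / 2.0
        # locate the edge (a, b) on the path containing the midpoint
        acc = 0.0
        for a, b, w in _path_edges(adj, path):
            if acc + w >= half - 1e-12:
                offset = half - acc  # distance from a along edge (a, b)
                return _reroot_on_edge(adj, a, b, w, offset)
            acc += w
        # numerical fallthrough: root next to the far end
        a, b, w = list(_path_edges(adj, path))[-1]
        return _reroot_on_edge(adj, a, b, w, w)


def _path_between(adj, src: Node, dst: Node) -> list[Node]:
    prev: dict[Node, Node] = {src: src}
    stack = [src]
    while stack:
        x = stack.pop()
        if x is dst:
            break
        for y, _ in adj[x]:
            if y not in prev:
                prev[y] = x
                stack.append(y)
    path = [dst]
    while path[-1] is not src:
        path.append(prev[path[-1]])
    return path[::-1]


def _path_edges(adj, path: list[Node]):
    for a, b in zip(path[:-1], path[1:]):
        w = next(w for y, w in adj[a] if y is b)
        yield a, b, w


def _reroot_on_edge(adj, a: Node, b: Node, w: float, offset: float) -> Node:
    """Build a rooted copy with the root ``offset`` from ``a`` on edge (a,b)."""

    def orient(orig: Node, new_node: Node, came_from: Node) -> None:
        for y, wy in adj[orig]:
            if y is came_from:
                continue
            child = Node(name=y.name)
            new_node.add(child, wy)
            orient(y, child, orig)

    root = Node()
    new_a, new_b = Node(name=a.name), Node(name=b.name)
    root.add(new_a, offset)
    root.add(new_b, w - offset)
    orient(a, new_a, b)
    orient(b, new_b, a)
    return root


def build_nj(dist: DistanceMatrix) -> NJTree:
    """Saitou–Nei neighbour joining.

    Joins the pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j at each step
    (ties broken toward the lexicographically first accession-index pair),
    with the standard branch-length and distance-update formulas. Negative
    branch lengths are clamped to zero; the original values are kept in
    ``diagnostics["negative_branches"]``.
    """
    n = dist.n
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 accessions")
    D = dist.d.astype(np.float64).copy()
    nodes: list[Node] = [Node(name=a) for a in dist.accession_ids]
    active = list(range(n))
    negatives: list[tuple[str, float]] = []

    def clamp(length: float, desc: str) -> float:
        if length < 0:
            negatives.append((desc, float(length)))
            return 0.0
        return float(length)

    next_id = 0
    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum -> lowest (i, j) pair
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        parent = Node()
        desc = f"node{next_id}"
        next_id += 1
        parent.add(nodes[i], clamp(li, f"{desc}->{nodes[i].name or 'internal'}"))
        parent.add(nodes[j], clamp(lj, f"{desc}->{nodes[j].name or 'internal'}"))
        # distances from the new node to every other active node
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = new_row
        D[active, k] = new_row
        D[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    # final three-way join around a hub
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    hub = Node()
    hub.add(nodes[a], clamp(la, f"hub->{nodes[a].name or 'internal'}"))
    hub.add(nodes[b], clamp(lb, f"hub->{nodes[b].name or 'internal'}"))
    hub.add(nodes[c], clamp(lc, f"hub->{nodes[c].name or 'internal'}"))
    return NJTree(hub, diagnostics={"negative_branches": negatives})


def classify_nj(
    tree: NJTree, labels: LabelSet, rooting: str = "midpoint"
) -> list[Prediction]:
    """Smallest-subtree majority classification on an NJ tree.

    For each query leaf, the level-1 neighbourhood is the leaf set of the
    smallest clade properly containing the query (after midpoint rooting);
    a strict majority (>50%) of the *other* leaves decides — the query's own
    label never votes for itself. With no majority the rule escalates exactly
    once to the next enclosing clade; if that also yields no majority the
    call is AMBIGUOUS. Rooting is a config option; only deterministic
    midpoint rooting is currently provided.
    """
    if rooting != "midpoint":
        raise ValueError(f"unknown rooting {rooting!r}")
    root = tree.midpoint_rooted()
    leaves = {leaf.name: leaf for leaf in root.leaves()}
    unlabelled = [a for a in leaves if a not in labels.labels]
    if unlabelled:
        raise ValueError(f"unlabelled leaves: {sorted(unlabelled)[:5]}")
    preds: list[Prediction] = []
    for name in tree.leaf_names:
        leaf = leaves[name]
        call = AMBIGUOUS
        level_used = None
        votes_used: dict[str, float] = {}
        node = leaf.parent
        for level in (1, 2):
            if node is None:
                break
            votes: dict[str, float] = {}
            for other in node.leaves():
                if other is leaf:
                    continue
                sp = labels[other.name]
                votes[sp] = votes.get(sp, 0) + 1
            winner = majority(votes)
            votes_used = votes
            if winner is not None:
                call = winner
                level_used = level
                break
            node = node.parent
        preds.append(
            Prediction(name, call, support={"level": level_used, "votes": votes_used})
        )
    return preds
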