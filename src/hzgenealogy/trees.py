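"""Core genealogical tree container.

A :class:`GenomeTree` is one rooted local genealogy together with the
half-open genomic interval ``[start, end)`` it spans.  Nodes are integer
indices into flat arrays (parent pointers, ages, labels), which keeps the
quartet-counting and TMRCA machinery vectorisable.  Node ages are in
whatever unit the input carries (generations for simulated trees); leaves
sit at age 0 unless the input says otherwise.  Polytomies are permitted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["GenomeTree", "random_coalescent_tree"]

NULL = -1


class GenomeTree:
    """Rooted genealogy over a genomic interval.

    Parameters
    ----------
    interval
        ``(start, end)`` in bp, 0-based half-open, ``start < end``.
    parent
        Integer array, ``parent[v]`` is the parent node of ``v`` or ``-1``
        for the root.  Exactly one root is required.
    time
        Node ages; every parent must be strictly older than its children.
    labels
        Sequence with one entry per node: haplotype id (str) for leaves,
        ``None`` for internal nodes.  Leaf labels must be unique.
    edge_length
        Optional per-node length of the edge to the parent.  When absent it
        is derived as ``time[parent] - time[child]``.  Kept separately so
        that non-ultrametric input trees round-trip exactly.
    """

    __slots__ = (
        "interval",
        "parent",
        "time",
        "labels",
        "edge_length",
        "root",
        "children",
        "_leaves",
        "_label_to_node",
        "_postorder",
        "_mrca_cache",
    )

    def __init__(
        self,
        interval: tuple[int, int],
        parent: Sequence[int],
        time: Sequence[float],
        labels: Sequence[str | None],
        edge_length: Sequence[float] | None = None,
    ):
        start, end = int(interval[0]), int(interval[1])
        if not start < end:
            raise ValueError(f"empty interval [{start}, {end})")
        self.interval = (start, end)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.time = np.asarray(time, dtype=np.float64)
        n = self.parent.shape[0]
        if self.time.shape[0] != n or len(labels) != n:
            raise ValueError("parent, time and labels must have equal length")
        self.labels = list(labels)

        roots = np.flatnonzero(self.parent == NULL)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])

        children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = int(self.parent[v])
            if p != NULL:
                # strictly-older is the rule; equality is tolerated so that
                # zero-length edges (e.g. clamped NJ branches) remain storable
                if self.time[p] < self.time[v]:
                    raise ValueError(
                        f"parent {p} (age {self.time[p]}) younger than "
                        f"child {v} (age {self.time[v]})"
                    )
                children[p].append(v)
        self.children = children

        self._leaves = [v for v in range(n) if not children[v]]
        for v in self._leaves:
            if self.labels[v] is None:
                raise ValueError(f"leaf node {v} is unlabelled")
        label_to_node = {self.labels[v]: v for v in self._leaves}
        if len(label_to_node) != len(self._leaves):
            raise ValueError("duplicate leaf labels")
        self._label_to_node = label_to_node

        if edge_length is None:
            el = np.zeros(n)
            has_parent = self.parent != NULL
            el[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
            self.edge_length = el
        else:
            self.edge_length = np.asarray(edge_length, dtype=np.float64)
            if self.edge_length.shape[0] != n:
                raise ValueError("edge_length length mismatch")
            if np.any(self.edge_length[self.parent != NULL] < 0):
                raise ValueError("negative edge length")
        self._postorder = None
        self._mrca_cache = None

    # ------------------------------------------------------------------ basics

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def leaves(self) -> list[int]:
        """Leaf node indices (tree order)."""
        return list(self._leaves)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[v] for v in self._leaves]

    @property
    def span(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def root_age(self) -> float:
        return float(self.time[self.root])

    def node_of(self, label: str) -> int:
        try:
            return self._label_to_node[label]
        except KeyError:
            raise KeyError(f"haplotype {label!r} is not a leaf of this tree") from None

    def has_leaf(self, label: str) -> bool:
        return label in self._label_to_node

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def postorder(self) -> list[int]:
        """Node indices, children always before parents."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            order.reverse()
            self._postorder = order
        return self._postorder

    def total_branch_length(self) -> float:
        mask = self.parent != NULL
        return float(self.edge_length[mask].sum())

    # ----------------------------------------------------------- MRCA queries

    def _leaf_tables(self):
        """Per-node descendant-leaf mask and all-pairs MRCA node matrix.

        Returns ``(leaf_nodes, leaf_pos, desc, mrca)`` where ``desc`` is a
        boolean ``(n_nodes, n_leaves)`` matrix and ``mrca[i, j]`` is the MRCA
        node index of leaves ``leaf_nodes[i]`` and ``leaf_nodes[j]``.
        Computed once per tree in a single postorder sweep: at each internal
        node, leaf pairs drawn from two distinct child subtrees have their
        MRCA exactly there.
        """
        if self._mrca_cache is not None:
            return self._mrca_cache
        n, leaves = self.n_nodes, self._leaves
        L = len(leaves)
        leaf_pos = {v: i for i, v in enumerate(leaves)}
        desc = np.zeros((n, L), dtype=bool)
        for v in leaves:
            desc[v, leaf_pos[v]] = True
        mrca = np.full((L, L), NULL, dtype=np.int64)
        np.fill_diagonal(mrca, np.asarray(leaves))
        for v in self.postorder():
            kids = self.children[v]
            if not kids:
                continue
            for a in range(len(kids)):
                da = desc[kids[a]]
                for b in range(a + 1, len(kids)):
                    db = desc[kids[b]]
                    block = np.ix_(np.flatnonzero(da), np.flatnonzero(db))
                    mrca[block] = v
                    mrca[block[1], block[0]] = v
                desc[v] |= da
        self._mrca_cache = (list(leaves), leaf_pos, desc, mrca)
        return self._mrca_cache

    def mrca(self, label_a: str, label_b: str) -> int:
        leaves, leaf_pos, _, mrca = self._leaf_tables()
        ia = leaf_pos[self.node_of(label_a)]
        ib = leaf_pos[self.node_of(label_b)]
        return int(mrca[ia, ib])

    def tmrca_matrix(self) -> tuple[list[str], np.ndarray]:
        """All-pairs TMRCA (age of the MRCA node) for the leaves.

        Returns the leaf labels (defining row/column order) and a symmetric
        matrix with zero diagonal.
        """
        leaves, _, _, mrca = self._leaf_tables()
        mat = self.time[mrca]
        np.fill_diagonal(mat, 0.0)
        return [self.labels[v] for v in leaves], mat

    # ------------------------------------------------------------------ misc

    def __repr__(self) -> str:  # pragma: no cover
        s, e = self.interval
        return f"GenomeTree([{s}, {e}), {self.n_leaves} leaves, root age {self.root_age:g})"


def random_coalescent_tree(
    labels: Iterable[str],
    rng: np.random.Generator,
    interval: tuple[int, int] = (0, 1),
    pair_rate: float = 1.0,
) -> GenomeTree:
    """Random dated, fully bifurcating tree on the given leaf labels.

    Pairs of lineages merge uniformly at random with exponential waiting
    times at total rate ``k*(k-1)/2 * pair_rate`` — a single-population
    Kingman coalescent, handy for null fixtures.
    """
    labels = list(labels)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 leaves")
    parent = list(np.full(2 * k - 1, NULL))
    time = [0.0] * (2 * k - 1)
    node_labels: list[str | None] = list(labels) + [None] * (k - 1)
    active = list(range(k))
    t = 0.0
    nxt = k
    while len(active) > 1:
        m = len(active)
        t += rng.exponential(1.0 / (m * (m - 1) / 2 * pair_rate))
        i, j = rng.choice(m, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return GenomeTree(interval, parent, time, node_labels)
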