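"""Neighbour-joining trees in fixed-SNP windows.

The window-tree route to a tree sequence: the genome is cut into
non-overlapping windows of exactly ``snps_per_window`` SNPs (50 by default),
a pairwise Hamming distance matrix over phased haplotypes is computed per
window, and a classic Saitou–Nei neighbour-joining tree is built for each.
Scaling the distances does not change the NJ topology, so raw mismatch
counts are used.  NJ trees are unrooted; midpoint rooting is applied for
storage so windows compose into a :class:`~hzgenealogy.treeio.TreeSequenceTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .treeio import PopulationMap, TreeSequenceTable, VariantTable
from .trees import NULL, GenomeTree

__all__ = ["DistanceMatrix", "snp_windows", "nj_tree", "window_nj_sequence"]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.any(np.isnan(self.d)):
            raise ValueError("NaN distances")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


@dataclass
class SnpWindow:
    interval: tuple[int, int]
    sites: np.ndarray  # indices into the VariantTable
    skipped: bool = False


def snp_windows(
    variants: VariantTable, snps_per_window: int = 50, min_per_ind: int = 15
) -> list[SnpWindow]:
    """Consecutive non-overlapping blocks of exactly ``snps_per_window`` SNPs.

    The trailing remainder is dropped.  A window is flagged ``skipped`` when
    any individual (haplotype pair) has fewer than ``min_per_ind`` genotyped
    sites in it — with fully imputed input this never triggers.
    """
    n = variants.n_sites
    if n < snps_per_window:
        raise ValueError(
            f"only {n} sites; need at least {snps_per_window} for one window"
        )
    out = []
    G = variants.genotypes
    for k in range(n // snps_per_window):
        sites = np.arange(k * snps_per_window, (k + 1) * snps_per_window)
        start = int(variants.positions[sites[0]])
        end = int(variants.positions[sites[-1]]) + 1
        block = G[sites]
        called = (block >= 0).sum(axis=0)  # per haplotype
        per_ind = called.reshape(-1, 2).min(axis=1) if called.size % 2 == 0 else called
        skipped = bool(np.any(per_ind < min_per_ind))
        out.append(SnpWindow((start, end), sites, skipped))
    return out


def hamming_distances(variants: VariantTable, sites: np.ndarray) -> DistanceMatrix:
    """Raw pairwise mismatch counts over the given sites."""
    X = variants.genotypes[sites].astype(np.int16)
    n = X.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = np.abs(X - X[:, [i]]).sum(axis=0)
    np.fill_diagonal(d, 0)
    return DistanceMatrix(list(variants.haplotypes), d)


def _midpoint_root(ids, adj) -> GenomeTree:
    """Root an unrooted NJ tree (adjacency {node: {nbr: length}}) at the
    midpoint of the longest leaf-to-leaf path and convert to GenomeTree."""
    leaves = [v for v in adj if v < len(ids)]

    def paths_from(src):
        dist, prev = {src: 0.0}, {src: None}
        stack = [src]
        while stack:
            v = stack.pop()
            for w, L in adj[v].items():
                if w not in dist:
                    dist[w] = dist[v] + L
                    prev[w] = v
                    stack.append(w)
        return dist, prev

    best = (-1.0, None, None, None)
    for a in leaves:
        dist, prev = paths_from(a)
        b = max(leaves, key=lambda x: (dist[x], x))
        if dist[b] > best[0]:
            best = (dist[b], a, b, (dist, prev))
    total, a, b, (dist, prev) = best
    # walk from b back to a; find the edge containing total/2 from a
    path = [b]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    path.reverse()  # a ... b
    half = total / 2.0
    root_at_node, edge = None, None
    acc = 0.0
    for u, v in zip(path, path[1:]):
        L = adj[u][v]
        if acc + L >= half - 1e-12:
            if abs(acc + L - half) <= 1e-12 and v != b:
                root_at_node = v
            else:
                edge = (u, v, half - acc)
            break
        acc += L
    nodes = list(adj)
    if edge is not None:
        u, v, offset = edge
        r = max(nodes) + 1
        L = adj[u].pop(v)
        adj[v].pop(u)
        adj[r] = {u: offset, v: L - offset}
        adj[u][r] = offset
        adj[v][r] = L - offset
        root = r
    else:
        root = root_at_node if root_at_node is not None else path[0]

    # orient away from root
    parent_of = {root: None}
    stack, topo = [root], []
    while stack:
        v = stack.pop()
        topo.append(v)
        for w in adj[v]:
            if w != parent_of[v]:
                parent_of[w] = v
                stack.append(w)
    index = {v: i for i, v in enumerate(topo)}
    n = len(topo)
    parent = np.full(n, NULL, dtype=np.int64)
    blen = np.zeros(n)
    labels: list[str | None] = [None] * n
    for v in topo:
        i = index[v]
        p = parent_of[v]
        if p is not None:
            parent[i] = index[p]
            blen[i] = adj[v][p]
        if v < len(ids):
            labels[i] = ids[v]
    # ages: max path to descendant leaf (topo is preorder, walk in reverse)
    age = np.zeros(n)
    for v in topo[:0:-1]:
        i = index[v]
        p = parent[i]
        age[p] = max(age[p], age[i] + blen[i])
    return GenomeTree((0, 1), parent, age, labels, edge_length=blen)


def nj_tree(dm: DistanceMatrix, interval: tuple[int, int] = (0, 1)) -> GenomeTree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Q-matrix minimisation with ties broken by the lowest index pair;
    negative branch lengths are clamped to zero (count logged at DEBUG).
    The unrooted result is midpoint-rooted for storage.
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = dm.d.copy()
    active = list(range(n0))
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n0)}
    nxt = n0
    clamped = 0
    # index into D for each active node
    pos = {i: i for i in range(n0)}
    while len(active) > 3:
        m = len(active)
        idx = np.array([pos[v] for v in active])
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, k=1)
        Qu = Q[iu]
        k = int(np.argmin(Qu))  # first minimum → lowest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])
        vi, vj = active[i], active[j]
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            clamped += 1
            li = 0.0
        if lj < 0:
            clamped += 1
            lj = 0.0
        u = nxt
        nxt += 1
        adj[u] = {vi: li, vj: lj}
        adj[vi][u] = li
        adj[vj][u] = lj
        # distances from u to remaining
        newd = (sub[i] + sub[j] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        pos[u] = D.shape[0] - 1
        for t_, v in enumerate(active):
            if v in (vi, vj):
                continue
            D[pos[u], pos[v]] = D[pos[v], pos[u]] = newd[t_]
        active = [v for v in active if v not in (vi, vj)] + [u]
    # final 3-star
    a, b, c = active
    dab = D[pos[a], pos[b]]
    dac = D[pos[a], pos[c]]
    dbc = D[pos[b], pos[c]]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    u = nxt
    adj[u] = {}
    for v, L in ((a, la), (b, lb), (c, lc)):
        if L < 0:
            clamped += 1
            L = 0.0
        adj[u][v] = L
        adj[v][u] = L
    if clamped:
        log.debug("clamped %d negative NJ branch lengths to zero", clamped)
    tree = _midpoint_root(dm.ids, adj)
    tree.interval = (int(interval[0]), int(interval[1]))
    return tree


def window_nj_sequence(
    variants: VariantTable,
    popmap: PopulationMap | None = None,
    snps_per_window: int = 50,
    min_per_ind: int = 15,
    chrom: str | None = None,
) -> TreeSequenceTable:
    """NJ tree per 50-SNP window, composed into a tree sequence.

    Windows with zero variation (all pairwise distances 0) or failing the
    ``min_per_ind`` filter are skipped with a warning.
    """
    trees = []
    for win in snp_windows(variants, snps_per_window, min_per_ind):
        if win.skipped:
            log.warning("window %s skipped: too few genotyped sites", win.interval)
            continue
        dm = hamming_distances(variants, win.sites)
        if not np.any(dm.d):
            log.warning("window %s skipped: no variation", win.interval)
            continue
        trees.append(nj_tree(dm, win.interval))
    return TreeSequenceTable(trees, chrom=chrom or variants.chrom)
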