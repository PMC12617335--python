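"""Topology weighting for four population groups.

For every marginal tree, the weight of each of the three possible unrooted
quartet ("group-level") topologies is the proportion of one-leaf-per-
population subsamples whose induced quartet shows that topology:

* ``GEO``  — samples cluster by hybrid zone: ((AveS, AveP), (PlaS, PlaP));
* ``VAR``  — samples cluster by flower-colour variety: ((AveS, PlaS), (AveP, PlaP));
* ``ALT``  — the remaining pairing: ((AveP, PlaS), (AveS, PlaP)).

Weights can be computed exactly (all ``n1*n2*n3*n4`` quartets, vectorised
over the tree's MRCA tables) or by fixed-size uniform sampling with
replacement (the ``fixed`` method, default 10,000 subtrees).  Polytomies
yield unresolved quartets whose mass is kept as a separate residual ``u``
rather than redistributed, so ``w_geo + w_var + w_alt + u = 1`` always, with
``u = 0`` for fully bifurcating trees.

Classification is on the *unrooted* induced quartet: the pairing ``ab|cd``
holds iff the subtree under ``MRCA(a, b)`` excludes ``c`` and ``d`` (or the
symmetric condition for ``c, d``) — a criterion invariant to re-rooting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import PopulationMap, TreeSequenceTable
from .trees import GenomeTree

__all__ = [
    "TOPOLOGIES",
    "GROUP_PAIRINGS",
    "TopologyWeights",
    "classify_quartet",
    "weight_tree_exact",
    "weight_tree_sampled",
    "weight_sequence",
]

TOPOLOGIES = ("geo", "var", "alt")

# population order fixed as (AveP, AveS, PlaP, PlaS); each pairing lists the
# two populations forming one side of the quartet split, the other two form
# the opposite side
GROUP_PAIRINGS = {
    "geo": (("AveS", "AveP"), ("PlaS", "PlaP")),
    "var": (("AveS", "PlaS"), ("AveP", "PlaP")),
    "alt": (("AveP", "PlaS"), ("AveS", "PlaP")),
}

EXACT_LIMIT = 10_000_000


@dataclass
class TopologyWeights:
    """Per-tree topology weights with sampling metadata."""

    interval: tuple[int, int]
    w_geo: float
    w_var: float
    w_alt: float
    u: float  # unresolved (polytomy) residual
    n_evaluated: int
    method: str  # "exact" | "sampled"

    def as_dict(self) -> dict:
        return {
            "start": self.interval[0],
            "end": self.interval[1],
            "w_geo": self.w_geo,
            "w_var": self.w_var,
            "w_alt": self.w_alt,
            "u": self.u,
            "n": self.n_evaluated,
            "method": self.method,
        }


def _group_leaf_indices(tree: GenomeTree, popmap: PopulationMap) -> dict[str, np.ndarray]:
    """Leaf-table indices of each population's haplotypes present in the tree."""
    popmap.require_four_populations()
    leaves, leaf_pos, _, _ = tree._leaf_tables()
    out: dict[str, list[int]] = {p: [] for p in popmap.populations}
    for v in leaves:
        pop = popmap.haplotype_to_pop.get(tree.labels[v])
        if pop is not None:
            out[pop].append(leaf_pos[v])
    for p, idx in out.items():
        if not idx:
            raise ValueError(f"population {p} has no leaves in this tree")
    return {p: np.asarray(idx) for p, idx in out.items()}


def _pairing_indices(groups: dict[str, np.ndarray], topology: str):
    (p, q), (r, s) = GROUP_PAIRINGS[topology]
    return groups[p], groups[q], groups[r], groups[s]


def classify_quartet(tree: GenomeTree, leaves: dict[str, str] | list[str]) -> str:
    """Classify the induced quartet of one haplotype per population.

    ``leaves`` maps population name → haplotype id (or is a list of 4
    haplotype ids in population order AveP, AveS, PlaP, PlaS).  Returns
    ``"geo"``, ``"var"``, ``"alt"`` or ``"unresolved"`` (star quartet).
    """
    if not isinstance(leaves, dict):
        leaves = dict(zip(("AveP", "AveS", "PlaP", "PlaS"), leaves))
    _, leaf_pos, desc, mrca = tree._leaf_tables()
    idx = {p: leaf_pos[tree.node_of(h)] for p, h in leaves.items()}
    if len(set(idx.values())) != 4:
        raise ValueError("quartet leaves must be 4 distinct haplotypes")
    for topo, ((p, q), (r, s)) in GROUP_PAIRINGS.items():
        a, b, c, d = idx[p], idx[q], idx[r], idx[s]
        m1 = mrca[a, b]
        m2 = mrca[c, d]
        if (not desc[m1, c] and not desc[m1, d]) or (not desc[m2, a] and not desc[m2, b]):
            return topo
    return "unresolved"


def _exact_counts(tree: GenomeTree, groups: dict[str, np.ndarray]) -> tuple[dict[str, int], int]:
    _, _, desc, mrca = tree._leaf_tables()
    nd = ~desc  # nd[node, leaf]: leaf NOT below node
    counts = {}
    total = int(np.prod([len(v) for v in groups.values()]))
    for topo in TOPOLOGIES:
        A, B, C, D = _pairing_indices(groups, topo)
        mab = mrca[np.ix_(A, B)]  # (a, b)
        mcd = mrca[np.ix_(C, D)]  # (c, d)
        # cherry (a,b) excludes both c and d
        cond1 = nd[mab][:, :, C][:, :, :, None] & nd[mab][:, :, D][:, :, None, :]
        # cherry (c,d) excludes both a and b  → axes (c, d, a, b) → transpose
        cond2 = nd[mcd][:, :, A][:, :, :, None] & nd[mcd][:, :, B][:, :, None, :]
        counts[topo] = int(
            np.count_nonzero(cond1 | cond2.transpose(2, 3, 0, 1))
        )
    return counts, total


def weight_tree_exact(tree: GenomeTree, popmap: PopulationMap) -> TopologyWeights:
    """Exact weights over all one-per-population quartets (equals enumeration)."""
    groups = _group_leaf_indices(tree, popmap)
    total = int(np.prod([len(v) for v in groups.values()]))
    if total > EXACT_LIMIT:
        raise ValueError(
            f"{total} quartets exceed the exact-mode limit; use weight_tree_sampled"
        )
    counts, total = _exact_counts(tree, groups)
    w = {t: counts[t] / total for t in TOPOLOGIES}
    u = (total - sum(counts.values())) / total
    return TopologyWeights(tree.interval, w["geo"], w["var"], w["alt"], u, total, "exact")


def weight_tree_sampled(
    tree: GenomeTree,
    popmap: PopulationMap,
    n_subtrees: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> TopologyWeights:
    """Fixed-size sampling: ``n_subtrees`` quartets uniform with replacement."""
    if n_subtrees <= 0:
        raise ValueError("n_subtrees must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.Generator(np.random.PCG64(seed))
    )
    groups = _group_leaf_indices(tree, popmap)
    _, _, desc, mrca = tree._leaf_tables()
    nd = ~desc
    pick = {
        p: idx[rng.integers(0, len(idx), size=n_subtrees)] for p, idx in groups.items()
    }
    counts = {}
    resolved = np.zeros(n_subtrees, dtype=bool)
    for topo, ((p, q), (r, s)) in GROUP_PAIRINGS.items():
        a, b, c, d = pick[p], pick[q], pick[r], pick[s]
        m1 = mrca[a, b]
        m2 = mrca[c, d]
        hit = (nd[m1, c] & nd[m1, d]) | (nd[m2, a] & nd[m2, b])
        counts[topo] = int(hit.sum())
        resolved |= hit
    u = float((~resolved).mean())
    w = {t: counts[t] / n_subtrees for t in TOPOLOGIES}
    return TopologyWeights(
        tree.interval, w["geo"], w["var"], w["alt"], u, n_subtrees, "sampled"
    )


def weight_sequence(
    table: TreeSequenceTable,
    popmap: PopulationMap,
    method: str = "auto",
    n_subtrees: int = 10_000,
    seed: int = 0,
) -> list[TopologyWeights]:
    """Weights for every tree in a sequence.

    ``method="auto"`` uses exact counting when the quartet count is at most
    ``EXACT_LIMIT`` and falls back to sampling otherwise; per-tree RNG
    streams derive from ``seed`` so results do not depend on tree order.
    """
    if method not in ("auto", "exact", "sampled", "fixed"):
        raise ValueError(f"unknown method {method!r}")
    out = []
    for w, tree in enumerate(table):
        use = method
        if method == "auto":
            groups = _group_leaf_indices(tree, popmap)
            total = int(np.prod([len(v) for v in groups.values()]))
            use = "exact" if total <= EXACT_LIMIT else "sampled"
        if use == "exact":
            out.append(weight_tree_exact(tree, popmap))
        else:
            rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, w])))
            out.append(weight_tree_sampled(tree, popmap, n_subtrees, rng))
    return out


def weights_dataframe(weights: list[TopologyWeights], chrom: str = "chr1"):
    """Tidy per-tree weight table (chrom, start, end, w_geo, w_var, w_alt, u, ...)."""
    import pandas as pd

    df = pd.DataFrame([w.as_dict() for w in weights])
    if len(df):
        df.insert(0, "chrom", chrom)
    return df
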