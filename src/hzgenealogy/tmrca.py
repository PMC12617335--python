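"""Pairwise TMRCA summaries, locus/flank contrasts and weight correlations.

For each dated marginal tree, the time to the most recent common ancestor
is computed for every haplotype pair, then summarised as the median over
three pair sets: within variety *pseudomajus* (PlaP + AveP haplotypes),
within variety *striatum* (PlaS + AveS), and between the two varieties.
Selective sweeps purge diversity and shorten within-variety TMRCAs at the
swept locus; barrier loci resist introgression and deepen between-variety
TMRCAs — the locus-versus-flank contrasts and the correlation between a
tree's T_var weight and its median TMRCAs test exactly these signatures.

Medians use the midpoint convention for even pair counts.  "Individuals"
are haplotypes by default; ``diploid=True`` averages each individual's two
haplotypes before taking medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scanstats import spearman_rho
from .treeio import PopulationMap, TreeSequenceTable
from .trees import GenomeTree

__all__ = [
    "LocusSpec",
    "pairwise_tmrca",
    "group_median_tmrca",
    "tmrca_summaries",
    "locus_flank_contrast",
    "weight_tmrca_correlation",
]

GROUPINGS = ("within_P", "within_S", "between")


@dataclass
class LocusSpec:
    """A candidate locus inside a larger analysed region."""

    chrom: str
    locus: tuple[int, int]
    region: tuple[int, int]

    def __post_init__(self):
        (ls, le), (rs, re) = self.locus, self.region
        if not (rs <= ls < le <= re):
            raise ValueError("locus must lie within the region")
        if ls == rs and le == re:
            raise ValueError("flanks are empty: locus equals region")

    def side_of(self, interval: tuple[int, int]) -> str:
        """Assign a tree to 'locus' or 'flank' by interval midpoint."""
        mid = (interval[0] + interval[1]) / 2.0
        return "locus" if self.locus[0] <= mid < self.locus[1] else "flank"


def pairwise_tmrca(tree: GenomeTree) -> tuple[list[str], np.ndarray]:
    """All-pairs MRCA ages; symmetric, zero diagonal, max equals root age."""
    return tree.tmrca_matrix()


def _pair_values(
    labels: list[str],
    mat: np.ndarray,
    popmap: PopulationMap,
    grouping: str,
    diploid: bool = False,
) -> np.ndarray:
    pos = {h: i for i, h in enumerate(labels)}
    if diploid:
        # average each diploid's two haplotypes (<ind>_a / <ind>_b) first
        inds: dict[str, list[int]] = {}
        for h, i in pos.items():
            inds.setdefault(h.rsplit("_", 1)[0], []).append(i)
        units = {ind: idx for ind, idx in inds.items()}
        unit_pop = {ind: popmap.haplotype_to_pop[labels[idx[0]]] for ind, idx in units.items()}

        def unit_value(u1, u2):
            block = mat[np.ix_(units[u1], units[u2])]
            return float(block.mean())

        names = sorted(units)
        of_variety = lambda u: popmap.variety[unit_pop[u]]  # noqa: E731
    else:
        names = [h for h in labels if h in popmap.haplotype_to_pop]
        of_variety = lambda h: popmap.variety[popmap.haplotype_to_pop[h]]  # noqa: E731

        def unit_value(h1, h2):
            return float(mat[pos[h1], pos[h2]])

    P = [u for u in names if of_variety(u) == "pseudomajus"]
    S = [u for u in names if of_variety(u) == "striatum"]
    if grouping == "within_P":
        group = P
    elif grouping == "within_S":
        group = S
    elif grouping == "between":
        if not P or not S:
            raise ValueError("both varieties must be present for 'between'")
        return np.array([unit_value(a, b) for a in P for b in S])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if len(group) < 2:
        raise ValueError(f"grouping {grouping} needs at least 2 members")
    return np.array(
        [unit_value(group[i], group[j]) for i in range(len(group)) for j in range(i + 1, len(group))]
    )


def group_median_tmrca(
    tree: GenomeTree, popmap: PopulationMap, grouping: str, diploid: bool = False
) -> float:
    """Median pairwise TMRCA over the grouping's pair set.

    Within-variety groupings pool both zones' haplotypes of that variety;
    'between' uses all cross-variety pairs.  np.median applies the midpoint
    convention for even pair counts.
    """
    labels, mat = tree.tmrca_matrix()
    return float(np.median(_pair_values(labels, mat, popmap, grouping, diploid)))


def tmrca_summaries(
    table: TreeSequenceTable,
    popmap: PopulationMap,
    weights=None,
    diploid: bool = False,
) -> pd.DataFrame:
    """Per-tree median TMRCAs (within_P, within_S, between) + optional w_var."""
    rows = []
    for i, tree in enumerate(table):
        labels, mat = tree.tmrca_matrix()
        row = {"start": tree.interval[0], "end": tree.interval[1]}
        for grouping in GROUPINGS:
            row[grouping] = float(
                np.median(_pair_values(labels, mat, popmap, grouping, diploid))
            )
        if weights is not None:
            row["w_var"] = weights[i].w_var
        rows.append(row)
    return pd.DataFrame(rows)


def locus_flank_contrast(summaries: pd.DataFrame, locus: LocusSpec) -> dict:
    """Split per-tree medians into locus vs flank distributions.

    Returns, per grouping, both full distributions (boxplot-ready) and the
    median-of-medians per side.
    """
    sides = summaries.apply(
        lambda r: locus.side_of((r["start"], r["end"])), axis=1
    )
    out: dict = {"n_locus": int((sides == "locus").sum()), "n_flank": int((sides == "flank").sum())}
    if out["n_locus"] == 0 or out["n_flank"] == 0:
        raise ValueError("one side of the contrast is empty")
    for grouping in GROUPINGS:
        loc = summaries.loc[sides == "locus", grouping].to_numpy()
        fla = summaries.loc[sides == "flank", grouping].to_numpy()
        out[grouping] = {
            "locus": loc,
            "flank": fla,
            "locus_median": float(np.median(loc)),
            "flank_median": float(np.median(fla)),
        }
    return out


def weight_tmrca_correlation(
    summaries: pd.DataFrame,
    grouping: str,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho between T_var weight and the grouping's median TMRCA,
    with a two-sided permutation p-value from seeded label shuffles."""
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    if "w_var" not in summaries.columns:
        raise ValueError("summaries lack a w_var column")
    if len(summaries) < 10:
        raise ValueError("need at least 10 trees")
    w = summaries["w_var"].to_numpy(dtype=float)
    t = summaries[grouping].to_numpy(dtype=float)
    if np.all(w == w[0]) or np.all(t == t[0]):
        raise ValueError("constant input")
    rho = spearman_rho(w, t)
    # permutation null: rank once, shuffle one margin, Pearson of ranks
    from scipy.stats import rankdata

    rw = rankdata(w)
    rt = rankdata(t)
    rw = (rw - rw.mean()) / rw.std()
    rt = (rt - rt.mean()) / rt.std()
    rng = np.random.Generator(np.random.PCG64(seed))
    n = rw.size
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = float(rw @ rng.permutation(rt)) / n
    p = (np.count_nonzero(np.abs(null) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1)
    return rho, float(p)
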