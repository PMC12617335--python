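"""Structured-coalescent simulator of replicated secondary-contact hybrid zones.

The model mirrors the demographic structure used for the snapdragon hybrid
zones: an ancestral population (size ``N_anc``) splits into the two flower
colour varieties at ``T_split_var`` generations ago (sizes ``N1``/``N2``);
within each variety, the two hybrid-zone populations are colonised at
``T_col``; and from ``T_sc`` generations ago to the present, the two
varieties exchange migrants within each zone at (possibly asymmetric)
backwards rates ``m12`` (pseudomajus → striatum) and ``m21``.  Locus-specific
barriers reduce migration by a factor ``1 - b`` at selected windows, and
recent sweeps within one variety are approximated by a bottleneck epoch.

Recombination is represented as a sequence of marginal trees: one
independent structured-coalescent genealogy per fixed-size window (no ARG
linkage between windows — a documented simplification; all downstream
statistics here are per-tree).  Infinite-sites mutations are dropped on
branches at rate ``mu`` per bp per generation to produce phased biallelic
genotypes.

Time is in generations; the pairwise coalescence rate in a deme of diploid
size ``N`` is ``1/(2N)``.  Everything is deterministic given ``seed``: each
window gets its own child RNG stream, so per-window results do not depend
on how many windows are simulated.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .trees import NULL, GenomeTree
from .treeio import (
    PopulationMap,
    TreeSequenceTable,
    VariantTable,
    haplotype_names,
    write_popmap,
    write_tree_sequence,
    write_vcf,
)

__all__ = [
    "DemographyConfig",
    "SimulationOutput",
    "simulate_tree_sequence",
    "drop_mutations",
    "simulate",
    "write_outputs",
]

DEMES = ("AveP", "AveS", "PlaP", "PlaS")
DEME_VARIETY = ("pseudomajus", "striatum", "pseudomajus", "striatum")
# within-zone partner deme (other variety, same zone)
PARTNER = (1, 0, 3, 2)

MU_DEFAULT = 5.7e-9  # per bp per generation


@dataclass
class DemographyConfig:
    """All parameters of the secondary-contact generative model.

    Default sizes give per-bp diversity ``pi = 4*N*mu ≈ 0.009``, the
    genome-wide value reported for these snapdragons; split/contact times
    and migration rates are desk-scale choices producing a weak-divergence,
    high-gene-flow background against which barrier loci and sweeps stand
    out (see docs/methods.md).
    """

    n_haplotypes_per_deme: int = 10
    N_anc: float = 400_000.0
    N1: float = 400_000.0
    N2: float = 400_000.0
    N_deme: float = 400_000.0
    T_split_var: float = 600_000.0
    T_col: float = 150_000.0
    T_sc: float = 50_000.0
    m12: float = 2e-5
    m21: float = 2e-5
    growth1: float = 0.0
    growth2: float = 0.0
    barrier_loci: list = field(default_factory=list)  # [( (start,end), b ), ...]
    sweep_loci: list = field(default_factory=list)  # [( (start,end), variety, T_sweep, factor ), ...]
    chrom_length: int = 200_000
    window_bp: int = 2_000
    mu: float = MU_DEFAULT
    seed: int = 1
    sweep_cap: float | None = None  # generations; default 20 * 2*N_deme*factor per sweep
    chrom: str = "chr1"

    def __post_init__(self):
        if not (0 <= self.T_sc < self.T_col < self.T_split_var):
            raise ValueError("require 0 <= T_sc < T_col < T_split_var")
        if self.m12 < 0 or self.m21 < 0:
            raise ValueError("migration rates must be non-negative")
        for N in (self.N_anc, self.N1, self.N2, self.N_deme):
            if N <= 0:
                raise ValueError("population sizes must be positive")
        if self.n_haplotypes_per_deme < 1:
            raise ValueError("need at least one haplotype per deme")
        if self.chrom_length % self.window_bp:
            raise ValueError("windows must tile [0, chrom_length) exactly")
        for (s, e), b in self.barrier_loci:
            if not 0 <= b <= 1:
                raise ValueError(f"barrier strength b={b} outside [0, 1]")
            if not 0 <= s < e <= self.chrom_length:
                raise ValueError(f"barrier interval ({s}, {e}) outside chromosome")
        for (s, e), variety, t_sweep, factor in self.sweep_loci:
            if variety not in ("pseudomajus", "striatum"):
                raise ValueError(f"unknown sweep variety {variety!r}")
            if t_sweep < 0 or factor <= 0:
                raise ValueError("sweep time must be >= 0 and bottleneck factor > 0")

    @property
    def n_windows(self) -> int:
        return self.chrom_length // self.window_bp

    def windows(self) -> np.ndarray:
        w = self.window_bp
        starts = np.arange(self.n_windows, dtype=np.int64) * w
        return np.stack([starts, starts + w], axis=1)

    @classmethod
    def panmictic(cls, N: float = 400_000.0, n_haplotypes_per_deme: int = 10, **kw) -> "DemographyConfig":
        """Effectively panmictic preset: all structure collapses within the
        first 3 generations, negligible against coalescent time scales."""
        kw.setdefault("chrom_length", 200_000)
        kw.setdefault("window_bp", 2_000)
        return cls(
            n_haplotypes_per_deme=n_haplotypes_per_deme,
            N_anc=N, N1=N, N2=N, N_deme=N,
            T_split_var=3.0, T_col=2.0, T_sc=1.0,
            m12=0.0, m21=0.0, **kw,
        )

    # ------------------------------------------------------ key-value config

    def to_file(self, path: str | os.PathLike):
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                if k == "barrier_loci":
                    v = ";".join(f"{s}-{e}:{b:g}" for (s, e), b in self.barrier_loci)
                elif k == "sweep_loci":
                    v = ";".join(
                        f"{s}-{e}:{var}:{t:g}:{f:g}"
                        for (s, e), var, t, f in self.sweep_loci
                    )
                fh.write(f"{k} = {v}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "DemographyConfig":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                kv[k.strip()] = v.strip()
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name not in kv:
                continue
            raw = kv[f_.name]
            if f_.name == "barrier_loci":
                kwargs[f_.name] = [
                    ((int(p.split("-")[0]), int(p.split("-")[1].split(":")[0])),
                     float(p.split(":")[1]))
                    for p in raw.split(";") if p
                ]
            elif f_.name == "sweep_loci":
                out = []
                for p in raw.split(";"):
                    if not p:
                        continue
                    span, var, t, fac = p.split(":")
                    s, e = span.split("-")
                    out.append(((int(s), int(e)), var, float(t), float(fac)))
                kwargs[f_.name] = out
            elif f_.name == "chrom":
                kwargs[f_.name] = raw
            elif f_.name in ("n_haplotypes_per_deme", "chrom_length", "window_bp", "seed"):
                kwargs[f_.name] = int(raw)
            elif f_.name == "sweep_cap":
                kwargs[f_.name] = None if raw == "None" else float(raw)
            else:
                kwargs[f_.name] = float(raw)
        return cls(**kwargs)


@dataclass
class SimulationOutput:
    """Trees, variants, population map and the per-window ground truth."""

    trees: TreeSequenceTable
    variants: VariantTable | None
    popmap: PopulationMap
    truth: "object"  # pandas DataFrame: start, end, barrier_b, migration_factor, sweep
    config: DemographyConfig


# ----------------------------------------------------------- coalescent core


def _window_factors(config: DemographyConfig, start: int, end: int):
    """Barrier migration factor and active sweeps for one window."""
    b = 0.0
    for (s, e), bb in config.barrier_loci:
        if s < end and start < e:
            b = max(b, bb)
    sweeps = []
    for (s, e), variety, t_sweep, factor in config.sweep_loci:
        if s < end and start < e:
            cap = (
                config.sweep_cap
                if config.sweep_cap is not None
                else 20.0 * 2.0 * config.N_deme * factor
            )
            sweeps.append({"variety": variety, "t": t_sweep, "factor": factor, "cap": cap})
    return b, sweeps


def _simulate_window_tree(
    config: DemographyConfig,
    interval: tuple[int, int],
    labels: list[str],
    deme_of_leaf: np.ndarray,
    rng: np.random.Generator,
    barrier_b: float,
    sweeps: list[dict],
) -> GenomeTree:
    """One structured-coalescent genealogy for one window.

    Lineages carry their current tip deme (0..3); the deme-grouping coarsens
    at ``T_col`` (zones merge within variety) and ``T_split_var`` (varieties
    merge).  Exponential growth in the tip demes is handled by closed-form
    waiting-time inversion; all other rates are piecewise constant between
    epoch boundaries.
    """
    n = len(labels)
    parent = np.full(2 * n - 1, NULL, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    node_labels: list[str | None] = list(labels) + [None] * (n - 1)

    lineage_deme = list(deme_of_leaf)  # index: lineage slot
    lineage_node = list(range(n))
    active = list(range(n))
    nxt = n

    mig_factor = 1.0 - barrier_b
    sweep_state = [dict(s, done=False) for s in sweeps]

    boundaries = sorted(
        {config.T_sc, config.T_col, config.T_split_var}
        | {s["t"] for s in sweep_state}
        | {s["t"] + s["cap"] for s in sweep_state}
    )
    growth_of_variety = {"pseudomajus": config.growth1, "striatum": config.growth2}

    t = 0.0
    while len(active) > 1:
        # epoch-dependent grouping of lineages
        if t < config.T_col:
            group_of = lambda d: d  # noqa: E731  (4 tip demes)
        elif t < config.T_split_var:
            group_of = lambda d: DEME_VARIETY[d]  # noqa: E731
        else:
            group_of = lambda d: "anc"  # noqa: E731

        groups: dict = {}
        for li in active:
            groups.setdefault(group_of(lineage_deme[li]), []).append(li)

        # sweep bottleneck factor per variety, deactivating once the swept
        # variety's lineages have coalesced to one (or the cap is passed)
        sweep_factor = {"pseudomajus": 1.0, "striatum": 1.0, None: 1.0}
        for s in sweep_state:
            if s["done"] or t < s["t"]:
                continue
            k_var = sum(
                1 for li in active if DEME_VARIETY[lineage_deme[li]] == s["variety"]
            )
            if k_var <= 1 or t >= s["t"] + s["cap"]:
                s["done"] = True
                continue
            sweep_factor[s["variety"]] = min(sweep_factor[s["variety"]], s["factor"])

        next_boundary = next((b for b in boundaries if b > t + 1e-12), math.inf)

        # candidate coalescence per group
        best_wait, best_event = math.inf, None
        for g, members in groups.items():
            k = len(members)
            if k < 2:
                continue
            pair_count = k * (k - 1) / 2
            if g == "anc":
                N, growth = config.N_anc, 0.0
            elif g == "pseudomajus":
                N, growth = config.N1 * sweep_factor["pseudomajus"], 0.0
            elif g == "striatum":
                N, growth = config.N2 * sweep_factor["striatum"], 0.0
            else:  # tip deme index
                variety = DEME_VARIETY[g]
                g_rate = growth_of_variety[variety]
                N = config.N_deme * sweep_factor[variety]
                if g_rate != 0.0:
                    if t < config.T_sc:
                        N = N * math.exp(-g_rate * t)
                        growth = g_rate
                    else:
                        N = N * math.exp(-g_rate * config.T_sc)
                        growth = 0.0
                else:
                    growth = 0.0
            lam = pair_count / (2.0 * N)
            E = rng.exponential()
            if growth == 0.0:
                wait = E / lam
            else:
                arg = 1.0 + growth * E / lam
                wait = math.log(arg) / growth if arg > 0 else math.inf
            if wait < best_wait:
                best_wait, best_event = wait, ("coal", g, members)

        # migration (between varieties within a zone, only during contact)
        if t < config.T_sc and mig_factor > 0.0:
            out_rate = []
            for li in active:
                d = lineage_deme[li]
                m = config.m12 if DEME_VARIETY[d] == "pseudomajus" else config.m21
                out_rate.append(m * mig_factor)
            total_m = float(np.sum(out_rate))
            if total_m > 0:
                wait = rng.exponential() / total_m
                if wait < best_wait:
                    p = np.asarray(out_rate) / total_m
                    li = active[int(rng.choice(len(active), p=p))]
                    best_wait, best_event = wait, ("mig", li)

        if t + best_wait >= next_boundary:
            t = next_boundary
            continue

        t += best_wait
        kind = best_event[0]
        if kind == "mig":
            li = best_event[1]
            lineage_deme[li] = PARTNER[lineage_deme[li]]
        else:
            _, g, members = best_event
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[i], members[j]
            parent[lineage_node[a]] = nxt
            parent[lineage_node[b]] = nxt
            time[nxt] = t
            # keep the merged lineage in slot a, in the same deme
            lineage_node[a] = nxt
            active.remove(b)
            nxt += 1

    return GenomeTree(interval, parent, time, node_labels)


def simulate_tree_sequence(config: DemographyConfig) -> SimulationOutput:
    """Simulate the marginal-tree sequence and per-window truth (no mutations)."""
    import pandas as pd

    popmap = PopulationMap.default(config.n_haplotypes_per_deme)
    labels, deme_of_leaf = [], []
    for d, pop in enumerate(DEMES):
        for h in haplotype_names(pop, config.n_haplotypes_per_deme):
            labels.append(h)
            deme_of_leaf.append(d)
    deme_of_leaf = np.asarray(deme_of_leaf)

    windows = config.windows()
    trees, truth_rows = [], []
    for w, (start, end) in enumerate(windows):
        b, sweeps = _window_factors(config, int(start), int(end))
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([config.seed, w]))
        )
        tree = _simulate_window_tree(
            config, (int(start), int(end)), labels, deme_of_leaf, rng, b, sweeps
        )
        trees.append(tree)
        truth_rows.append(
            {
                "start": int(start),
                "end": int(end),
                "barrier_b": b,
                "migration_factor": 1.0 - b,
                "sweep": bool(sweeps),
            }
        )
    table = TreeSequenceTable(trees, chrom=config.chrom)
    truth = pd.DataFrame(truth_rows)
    return SimulationOutput(table, None, popmap, truth, config)


# -------------------------------------------------------------------- mutate


def drop_mutations(
    trees: TreeSequenceTable, mu: float, seed: int, chrom: str | None = None
) -> VariantTable:
    """Drop infinite-sites mutations on branches (Poisson per branch).

    Each mutation creates one biallelic site: ancestral allele ``A`` carried
    outside, derived allele ``T`` carried by the descendants of the branch.
    Positions are uniform integers within the tree's window, unique by
    sampling without replacement (the infinite-sites idealisation at bp
    resolution).
    """
    haplotypes = trees[0].leaf_labels if len(trees) else []
    positions, rows = [], []
    for w, tree in enumerate(trees):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([seed, w, 0xA11E1E]))
        )
        start, end = tree.interval
        span = end - start
        blen = tree.edge_length.copy()
        blen[tree.root] = 0.0
        if np.any(blen < 0):
            raise ValueError("negative branch length")
        total = float(blen.sum())
        n_mut = int(rng.poisson(mu * span * total)) if total > 0 else 0
        if n_mut == 0:
            continue
        if n_mut > span:
            raise ValueError(
                f"window [{start},{end}) too short for {n_mut} infinite-site mutations"
            )
        pos = np.sort(rng.choice(span, size=n_mut, replace=False)) + start
        edges = rng.choice(tree.n_nodes, size=n_mut, p=blen / total)
        leaves, leaf_pos, desc, _ = tree._leaf_tables()
        # align columns to the table-wide haplotype order
        col_of = {tree.labels[leaves[i]]: i for i in range(len(leaves))}
        cols = [col_of[h] for h in haplotypes]
        for p, e in zip(pos, edges):
            positions.append(int(p))
            rows.append(desc[e][cols].astype(np.int8))
    geno = (
        np.asarray(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(haplotypes)), dtype=np.int8)
    )
    chrom = chrom or (trees.chrom if len(trees) else "chr1")
    n = len(positions)
    return VariantTable(chrom, positions, ["A"] * n, ["T"] * n, haplotypes, geno)


def simulate(config: DemographyConfig) -> SimulationOutput:
    """Full run: trees, truth, population map and mutated genotypes."""
    sim = simulate_tree_sequence(config)
    sim.variants = drop_mutations(sim.trees, config.mu, config.seed, chrom=config.chrom)
    return sim


# --------------------------------------------------------------------- write


def write_outputs(sim: SimulationOutput, prefix: str | os.PathLike) -> dict[str, str]:
    """Write VCF + tree-sequence TSV + popmap TSV + truth TSV; returns paths."""
    prefix = os.fspath(prefix)
    paths = {
        "trees": prefix + ".trees.tsv",
        "vcf": prefix + ".vcf",
        "popmap": prefix + ".popmap.tsv",
        "truth": prefix + ".truth.tsv",
        "config": prefix + ".config.txt",
    }
    write_tree_sequence(sim.trees, paths["trees"])
    if sim.variants is not None:
        write_vcf(sim.variants, paths["vcf"], contig_length=sim.config.chrom_length)
    write_popmap(sim.popmap, paths["popmap"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    sim.config.to_file(paths["config"])
    return paths
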