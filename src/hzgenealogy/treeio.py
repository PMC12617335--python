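"""I/O for tree sequences, population maps and phased VCF.

Formats
-------
* tree-sequence TSV: ``chrom  start  end  newick`` with 0-based half-open
  intervals, one marginal tree per row;
* population map TSV: ``haplotype_id  population  zone  variety``;
* VCF v4.2 with phased diploid ``GT`` columns — each sample contributes two
  haplotypes named ``<sample>_a`` and ``<sample>_b``.

Internally all coordinates are 0-based half-open; the VCF boundary converts
to/from 1-based positions.  Newick parsing is delegated to dendropy; ages
are reconstructed from branch lengths with leaves at age 0 (for a
non-ultrametric input, a node's age is its maximum path length to a
descendant leaf, and the original branch lengths are kept so round-trips
are exact).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .trees import NULL, GenomeTree

__all__ = [
    "PopulationMap",
    "TreeSequenceTable",
    "VariantTable",
    "parse_newick",
    "write_newick",
    "read_tree_sequence",
    "write_tree_sequence",
    "read_popmap",
    "write_popmap",
    "read_vcf",
    "write_vcf",
    "tree_sequence_summary",
]

POPULATIONS = ("AveP", "AveS", "PlaP", "PlaS")
ZONE = {"AveP": "Ave", "AveS": "Ave", "PlaP": "Pla", "PlaS": "Pla"}
VARIETY = {"AveP": "pseudomajus", "AveS": "striatum", "PlaP": "pseudomajus", "PlaS": "striatum"}


@dataclass
class PopulationMap:
    """Haplotype → population assignment for the four hybrid-zone demes.

    Populations are named ``<zone><variety-initial>``: zones ``Pla``
    (Planoles) and ``Ave`` (Avellanet); varieties ``P`` (*pseudomajus*,
    magenta) and ``S`` (*striatum*, yellow).
    """

    haplotype_to_pop: dict[str, str]
    zone: dict[str, str] = field(default_factory=lambda: dict(ZONE))
    variety: dict[str, str] = field(default_factory=lambda: dict(VARIETY))

    def __post_init__(self):
        pops = set(self.haplotype_to_pop.values())
        unknown = pops - set(self.zone) - set(self.variety)
        if unknown - set(self.zone):
            raise ValueError(f"populations without a zone: {sorted(unknown)}")
        for p in pops:
            if p not in self.variety:
                raise ValueError(f"population without a variety: {p}")

    @classmethod
    def default(cls, n_haplotypes_per_deme: int) -> "PopulationMap":
        """Even sampling of the four demes with the package's naming scheme."""
        hap_to_pop = {}
        for pop in POPULATIONS:
            for h in haplotype_names(pop, n_haplotypes_per_deme):
                hap_to_pop[h] = pop
        return cls(hap_to_pop)

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.haplotype_to_pop.values()))

    def haplotypes(self, pop: str) -> list[str]:
        return [h for h, p in self.haplotype_to_pop.items() if p == pop]

    def variety_haplotypes(self, variety: str) -> list[str]:
        return [
            h for h, p in self.haplotype_to_pop.items() if self.variety[p] == variety
        ]

    def require_four_populations(self):
        pops = self.populations
        if len(pops) != 4:
            raise ValueError(f"topology weighting needs exactly 4 populations, got {pops}")
        for p in pops:
            if not self.haplotypes(p):
                raise ValueError(f"population {p} is empty")


def haplotype_names(pop: str, n: int) -> list[str]:
    """Haplotype ids for ``n`` haplotypes: pairs ``<pop><k>_a``/``<pop><k>_b``."""
    out = []
    for i in range(n):
        out.append(f"{pop}{i // 2}_{'ab'[i % 2]}")
    return out


class TreeSequenceTable:
    """Ordered, non-overlapping marginal trees tiling (part of) a chromosome."""

    def __init__(self, trees: list[GenomeTree], chrom: str = "chr1"):
        self.chrom = chrom
        trees = sorted(trees, key=lambda t: t.interval)
        for a, b in zip(trees, trees[1:]):
            if b.interval[0] < a.interval[1]:
                raise ValueError(
                    f"overlapping tree intervals {a.interval} and {b.interval}"
                )
        self.trees = trees
        self.has_gaps = any(
            b.interval[0] > a.interval[1] for a, b in zip(trees, trees[1:])
        )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i) -> GenomeTree:
        return self.trees[i]

    @property
    def intervals(self) -> np.ndarray:
        return np.array([t.interval for t in self.trees], dtype=np.int64)


class VariantTable:
    """Biallelic phased variants: positions (0-based), alleles, 0/1 matrix."""

    def __init__(self, chrom, positions, ref, alt, haplotypes, genotypes):
        self.chrom = chrom
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref = list(ref)
        self.alt = list(alt)
        self.haplotypes = list(haplotypes)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        n_sites = self.positions.shape[0]
        if self.genotypes.shape != (n_sites, len(self.haplotypes)):
            raise ValueError("genotype matrix shape mismatch")
        if n_sites > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def columns(self, haplotype_ids) -> np.ndarray:
        idx = {h: i for i, h in enumerate(self.haplotypes)}
        return self.genotypes[:, [idx[h] for h in haplotype_ids]]


# --------------------------------------------------------------------- newick


def parse_newick(text: str, interval: tuple[int, int] = (0, 1)) -> GenomeTree:
    """Parse one newick string (branch lengths required on non-root edges)."""
    dt = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    nodes = list(dt.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, NULL, dtype=np.int64)
    blen = np.zeros(n)
    labels: list[str | None] = [None] * n
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ValueError("newick edge without a branch length")
            if nd.edge.length < 0:
                raise ValueError("negative branch length in newick input")
            blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise ValueError("unlabelled leaf in newick input")
            labels[i] = str(nd.taxon.label)
    # ages: max path length to a descendant leaf (postorder = reversed preorder)
    age = np.zeros(n)
    for i in range(n - 1, 0, -1):
        p = parent[i]
        age[p] = max(age[p], age[i] + blen[i])
    return GenomeTree(interval, parent, age, labels, edge_length=blen)


def _newick_node(tree: GenomeTree, v: int, out: list[str]):
    kids = tree.children[v]
    if kids:
        out.append("(")
        for i, c in enumerate(kids):
            if i:
                out.append(",")
            _newick_node(tree, c, out)
        out.append(")")
    else:
        out.append(tree.labels[v])
    if tree.parent[v] != NULL:
        out.append(f":{tree.edge_length[v]:.10g}")


def write_newick(tree: GenomeTree) -> str:
    out: list[str] = []
    _newick_node(tree, tree.root, out)
    out.append(";")
    return "".join(out)


# ------------------------------------------------------------- tree sequences


def write_tree_sequence(table: TreeSequenceTable, path: str | os.PathLike):
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tnewick\n")
        for t in table:
            s, e = t.interval
            fh.write(f"{table.chrom}\t{s}\t{e}\t{write_newick(t)}\n")


def read_tree_sequence(path: str | os.PathLike) -> TreeSequenceTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "newick"}
    if not required <= set(df.columns):
        raise ValueError(f"tree-sequence TSV needs columns {sorted(required)}")
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError("one chromosome per tree-sequence file")
    trees = [
        parse_newick(row.newick, (int(row.start), int(row.end)))
        for row in df.itertuples()
    ]
    return TreeSequenceTable(trees, chrom=str(chroms[0]) if len(chroms) else "chr1")


# ----------------------------------------------------------------- popmap TSV


def write_popmap(popmap: PopulationMap, path: str | os.PathLike):
    with open(path, "w") as fh:
        fh.write("haplotype_id\tpopulation\tzone\tvariety\n")
        for h, p in popmap.haplotype_to_pop.items():
            fh.write(f"{h}\t{p}\t{popmap.zone[p]}\t{popmap.variety[p]}\n")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"haplotype_id", "population", "zone", "variety"}
    if not required <= set(df.columns):
        raise ValueError(f"popmap TSV needs columns {sorted(required)}")
    hap_to_pop = dict(zip(df["haplotype_id"], df["population"]))
    if len(hap_to_pop) != len(df):
        raise ValueError("duplicate haplotype ids in popmap")
    zone = dict(zip(df["population"], df["zone"]))
    variety = dict(zip(df["population"], df["variety"]))
    return PopulationMap(hap_to_pop, zone=zone, variety=variety)


# ------------------------------------------------------------------------ VCF


def write_vcf(variants: VariantTable, path: str | os.PathLike, contig_length: int | None = None):
    """Write phased diploid VCF v4.2; consecutive ``_a``/``_b`` haplotypes pair."""
    haps = variants.haplotypes
    if len(haps) % 2:
        raise ValueError("odd number of haplotypes cannot be paired into diploids")
    samples = []
    for i in range(0, len(haps), 2):
        a, b = haps[i], haps[i + 1]
        if not (a.endswith("_a") and b.endswith("_b") and a[:-2] == b[:-2]):
            raise ValueError(f"haplotypes {a!r}, {b!r} do not form a diploid pair")
        samples.append(a[:-2])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_length is None:
            contig_length = int(variants.positions[-1]) + 1 if variants.n_sites else 1
        fh.write(f"##contig=<ID={variants.chrom},length={contig_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        G = variants.genotypes
        for k in range(variants.n_sites):
            gts = "\t".join(
                f"{G[k, i]}|{G[k, i + 1]}" for i in range(0, len(haps), 2)
            )
            fh.write(
                f"{variants.chrom}\t{variants.positions[k] + 1}\t.\t"
                f"{variants.ref[k]}\t{variants.alt[k]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> VariantTable:
    """Read a phased biallelic VCF into a VariantTable (positions → 0-based)."""
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = vcf.samples
    haps = [f"{s}_{x}" for s in samples for x in "ab"]
    chrom = None
    positions, ref, alt, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic site at {var.CHROM}:{var.POS}")
        chrom = var.CHROM
        positions.append(var.POS - 1)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        g = np.asarray(var.genotypes)  # (n_samples, 3): a, b, phased flag
        if np.any(g[:, :2] < 0):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        rows.append(g[:, :2].reshape(-1))
    vcf.close()
    geno = (
        np.asarray(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(haps)), dtype=np.int8)
    )
    return VariantTable(chrom or "chr1", positions, ref, alt, haps, geno)


# -------------------------------------------------------------------- summary


def tree_sequence_summary(table: TreeSequenceTable, variants: VariantTable | None) -> dict:
    """Tree-sequence characteristics: tree count, span, SNPs per tree.

    Each SNP is assigned to the unique tree whose half-open interval contains
    its position; SNPs outside every interval are counted separately so
    totals are conserved.
    """
    spans = np.array([t.span for t in table], dtype=float)
    n_trees = len(table)
    counts = np.zeros(n_trees, dtype=np.int64)
    unassigned = 0
    if variants is not None and variants.n_sites and n_trees:
        iv = table.intervals
        idx = np.searchsorted(iv[:, 0], variants.positions, side="right") - 1
        ok = (idx >= 0) & (variants.positions < iv[np.clip(idx, 0, None), 1])
        unassigned = int((~ok).sum())
        np.add.at(counts, idx[ok], 1)
    return {
        "n_trees": n_trees,
        "mean_span_bp": float(spans.mean()) if n_trees else float("nan"),
        "sd_span_bp": float(spans.std(ddof=0)) if n_trees else float("nan"),
        "mean_snps_per_tree": float(counts.mean()) if n_trees else float("nan"),
        "sd_snps_per_tree": float(counts.std(ddof=0)) if n_trees else float("nan"),
        "fraction_trees_without_snps": float((counts == 0).mean()) if n_trees else float("nan"),
        "n_snps_assigned": int(counts.sum()),
        "n_snps_unassigned": unassigned,
        "snps_per_tree": counts,
    }
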