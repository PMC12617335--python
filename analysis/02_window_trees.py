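#!/usr/bin/env python
"""Step 2 — rebuild genealogies from the genotypes alone.

Neighbour-joining trees in non-overlapping 50-SNP windows, mirroring how
trees are inferred when only phased SNPs are available.  Compare the
resulting tree sequence summary to the simulator's true marginal trees.
"""

import argparse
import json

from hzgenealogy.treeio import (
    read_popmap,
    read_tree_sequence,
    read_vcf,
    tree_sequence_summary,
    write_tree_sequence,
)
from hzgenealogy.windowtrees import window_nj_sequence


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--prefix", default="results/data/replicate")
    ap.add_argument("--out", default="results/data/replicate.nj.trees.tsv")
    args = ap.parse_args()

    variants = read_vcf(args.prefix + ".vcf")
    popmap = read_popmap(args.prefix + ".popmap.tsv")
    nj = window_nj_sequence(variants, popmap, snps_per_window=50)
    write_tree_sequence(nj, args.out)

    true = read_tree_sequence(args.prefix + ".trees.tsv")
    report = {
        "true_trees": {k: v for k, v in tree_sequence_summary(true, variants).items()
                       if k != "snps_per_tree"},
        "nj_trees": {k: v for k, v in tree_sequence_summary(nj, variants).items()
                     if k != "snps_per_tree"},
        "out": args.out,
    }
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
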