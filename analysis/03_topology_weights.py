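#!/usr/bin/env python
"""Step 3 — topology weighting of the marginal trees.

Exact T_geo / T_var / T_alt weights per tree for both the true simulated
trees and the NJ window trees, plus the raw T_var outlier calls at the 0.55
(strict >) and 0.60 (>=) thresholds.
"""

import argparse
import json

import numpy as np

from hzgenealogy.scanstats import tvar_outliers
from hzgenealogy.treeio import read_popmap, read_tree_sequence
from hzgenealogy.twisst import weight_sequence, weights_dataframe


def weigh(trees_path, popmap, out):
    table = read_tree_sequence(trees_path)
    ws = weight_sequence(table, popmap, method="exact")
    df = weights_dataframe(ws, chrom=table.chrom)
    df.to_csv(out, sep="\t", index=False)
    calls = tvar_outliers(df)
    return df, {
        "n_trees": len(df),
        "mean_weights": {
            k: float(df[k].mean()) for k in ("w_geo", "w_var", "w_alt")
        },
        "n_tvar_gt_0.55": int(sum(c.flag for c in calls if c.threshold == 0.55)),
        "n_tvar_ge_0.60": int(sum(c.flag for c in calls if c.threshold == 0.60)),
        "out": out,
    }


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--prefix", default="results/data/replicate")
    args = ap.parse_args()

    popmap = read_popmap(args.prefix + ".popmap.tsv")
    report = {}
    _, report["true"] = weigh(
        args.prefix + ".trees.tsv", popmap, args.prefix + ".weights.tsv"
    )
    _, report["nj"] = weigh(
        args.prefix + ".nj.trees.tsv", popmap, args.prefix + ".nj.weights.tsv"
    )
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
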