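#!/usr/bin/env python
"""Step 5 — classical genome scan and landscape comparison.

Windowed pi, d_xy, Hudson F_ST and mean per-site Weir-Cockerham F_ST for
the within-zone population pair (PlaP vs PlaS), loess smoothing, 95th/99th
percentile outlier calls, and the Spearman correlation between the F_ST
landscape and the T_var weight landscape.
"""

import argparse
import json

import numpy as np
import pandas as pd

from hzgenealogy.scanstats import (
    loess_smooth,
    percentile_outliers,
    spearman_rho,
    window_scan,
)
from hzgenealogy.treeio import read_popmap, read_vcf


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--prefix", default="results/data/replicate")
    ap.add_argument("--pops", default="PlaP,PlaS")
    ap.add_argument("--window", type=int, default=10_000)
    ap.add_argument("--out", default="results/scan.tsv")
    args = ap.parse_args()

    variants = read_vcf(args.prefix + ".vcf")
    popmap = read_popmap(args.prefix + ".popmap.tsv")
    pop1, pop2 = args.pops.split(",")
    df = window_scan(variants, popmap, pop1, pop2, window_bp=args.window)
    ok = ~df["fst_hudson"].isna()
    mids = ((df["start"] + df["end"]) / 2).to_numpy(float)
    sm = np.full(len(df), np.nan)
    sm[ok.to_numpy()] = loess_smooth(
        mids[ok.to_numpy()], df.loc[ok, "fst_hudson"].to_numpy()
    )
    df["fst_hudson_loess"] = sm
    df.to_csv(args.out, sep="\t", index=False)

    report = {"n_windows": len(df), "out": args.out}
    for q in (95.0, 99.0):
        calls = percentile_outliers(df, "fst_hudson", q=q)
        report[f"n_outliers_q{q:g}"] = int(sum(c.flag for c in calls))

    # F_ST landscape vs T_var landscape (weights re-binned to scan windows)
    wdf = pd.read_csv(args.prefix + ".weights.tsv", sep="\t")
    wmids = ((wdf["start"] + wdf["end"]) / 2).to_numpy(float)
    bins = (wmids // args.window).astype(int)
    wvar = wdf.groupby(bins)["w_var"].mean()
    joined = df.loc[ok].assign(
        w_var=wvar.reindex(df.loc[ok, "start"] // args.window).to_numpy()
    ).dropna(subset=["w_var"])
    rho = spearman_rho(joined["fst_hudson"], joined["w_var"])
    report["spearman_fst_vs_wvar"] = rho
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
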