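"""Site and window population-genetic statistics and outlier scans.

Implements the scan toolkit used on the hybrid-zone data: per-site
Weir–Cockerham F_ST (two populations, variance components, phased
haplotypes treated as haploid samples), windowed Hudson F_ST
(``1 - pi_within / pi_between`` as a ratio of window averages), nucleotide
diversity ``pi`` and divergence ``d_xy`` per bp of callable window length,
tricube local-linear (loess) smoothing with a fixed bp bandwidth,
percentile and raw-threshold outlier calls, and Spearman rank correlation
between landscapes.

Conventions: windows are 10 kbp non-overlapping by default and masked below
``min_sites`` variants; negative F_ST estimates are reported, not clamped;
quantiles interpolate linearly between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .treeio import PopulationMap, VariantTable

__all__ = [
    "wc_fst_site",
    "wc_fst_sites",
    "pi_window",
    "dxy_window",
    "hudson_fst_window",
    "window_scan",
    "loess_smooth",
    "percentile_outliers",
    "tvar_outliers",
    "spearman_rho",
]


# ------------------------------------------------------------- per-site F_ST


def wc_fst_site(alleles1: np.ndarray, alleles2: np.ndarray) -> float:
    """Two-population Weir–Cockerham theta at one biallelic site.

    ``alleles1``/``alleles2`` are 0/1 arrays of haploid (phased haplotype)
    calls.  Computed from the variance components of the allele-frequency
    ANOVA: with mean squares between (MSP) and within (MSG) populations,

        theta = (MSP - MSG) / (MSP + (n_c - 1) * MSG).

    Returns NaN when the site is monomorphic across both populations
    (estimator undefined, 0/0).
    """
    a1 = np.asarray(alleles1)
    a2 = np.asarray(alleles2)
    n1, n2 = a1.size, a2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 sampled alleles per population")
    p1, p2 = a1.mean(), a2.mean()
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    if pbar in (0.0, 1.0):
        return float("nan")
    nc = (ntot - (n1 * n1 + n2 * n2) / ntot)  # r - 1 == 1
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r - 1) == 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
    denom = msp + (nc - 1) * msg
    if denom == 0:
        return float("nan")
    return float((msp - msg) / denom)


def wc_fst_sites(variants: VariantTable, popmap: PopulationMap, pop1: str, pop2: str) -> np.ndarray:
    """Per-site WC F_ST for every site (NaN where undefined)."""
    G1 = variants.columns(popmap.haplotypes(pop1))
    G2 = variants.columns(popmap.haplotypes(pop2))
    return np.array(
        [wc_fst_site(G1[k], G2[k]) for k in range(variants.n_sites)]
    )


# ---------------------------------------------------------- window diversity


def _pairwise_diffs_within(G: np.ndarray) -> float:
    """Sum over sites of mean pairwise differences within one sample set."""
    n = G.shape[1]
    c = G.sum(axis=1).astype(float)
    return float((c * (n - c)).sum() / (n * (n - 1) / 2.0))


def _pairwise_diffs_between(G1: np.ndarray, G2: np.ndarray) -> float:
    n1, n2 = G1.shape[1], G2.shape[1]
    p1 = G1.sum(axis=1).astype(float) / n1
    p2 = G2.sum(axis=1).astype(float) / n2
    return float((p1 * (1 - p2) + p2 * (1 - p1)).sum())


def pi_window(G: np.ndarray, length_bp: int) -> float:
    """Nucleotide diversity per bp: mean pairwise differences / window length."""
    if G.shape[1] < 2:
        raise ValueError("pi needs at least 2 haplotypes")
    return _pairwise_diffs_within(G) / length_bp


def dxy_window(G1: np.ndarray, G2: np.ndarray, length_bp: int) -> float:
    """Between-population divergence per bp of callable window length."""
    return _pairwise_diffs_between(G1, G2) / length_bp


def _freq_diffs_within(G: np.ndarray) -> float:
    """Sum over sites of within-population heterozygosity 2p(1-p)."""
    p = G.sum(axis=1).astype(float) / G.shape[1]
    return float((2.0 * p * (1.0 - p)).sum())


def hudson_fst_window(G1: np.ndarray, G2: np.ndarray) -> float:
    """Hudson F_ST = 1 - pi_within / pi_between (ratio of window averages).

    ``pi_within`` is the mean of the two within-population heterozygosities
    (frequency form, 2p(1-p) per site) and ``pi_between`` the raw d_xy
    numerator; the bp denominators cancel.  The frequency form makes the
    estimator exactly 0 when the two populations have identical allele
    frequencies at every site, and exactly 1 on fixed differences.
    Returns NaN when between-population diversity is zero.
    """
    pw = 0.5 * (_freq_diffs_within(G1) + _freq_diffs_within(G2))
    pb = _pairwise_diffs_between(G1, G2)
    if pb == 0:
        return float("nan")
    return float(1.0 - pw / pb)


def window_scan(
    variants: VariantTable,
    popmap: PopulationMap,
    pop1: str,
    pop2: str,
    window_bp: int = 10_000,
    min_sites: int = 10,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Windowed pi (both populations), d_xy, Hudson F_ST and mean per-site
    WC F_ST for one population pair.

    Denominators use the callable window length in bp (fully called input
    assumed); windows with fewer than ``min_sites`` variants are masked
    (statistics set to NaN, ``masked`` flag set).
    """
    if chrom_length is None:
        chrom_length = (
            (int(variants.positions[-1]) // window_bp + 1) * window_bp
            if variants.n_sites
            else window_bp
        )
    h1 = popmap.haplotypes(pop1)
    h2 = popmap.haplotypes(pop2)
    G1_all = variants.columns(h1)
    G2_all = variants.columns(h2)
    rows = []
    for start in range(0, chrom_length, window_bp):
        end = start + window_bp
        sel = (variants.positions >= start) & (variants.positions < end)
        G1, G2 = G1_all[sel], G2_all[sel]
        n_sites = int(sel.sum())
        row = {"start": start, "end": end, "n_sites": n_sites, "masked": n_sites < min_sites}
        if n_sites >= min_sites:
            row["pi1"] = pi_window(G1, window_bp)
            row["pi2"] = pi_window(G2, window_bp)
            row["dxy"] = dxy_window(G1, G2, window_bp)
            row["fst_hudson"] = hudson_fst_window(G1, G2)
            site_fst = np.array(
                [wc_fst_site(G1[k], G2[k]) for k in range(n_sites)]
            )
            defined = ~np.isnan(site_fst)
            row["fst_wc_mean"] = float(site_fst[defined].mean()) if defined.any() else np.nan
            row["n_fst_wc_undefined"] = int((~defined).sum())
        else:
            row.update(
                pi1=np.nan, pi2=np.nan, dxy=np.nan,
                fst_hudson=np.nan, fst_wc_mean=np.nan, n_fst_wc_undefined=0,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- loess


def loess_smooth(positions, values, span_bp: float = 50_000.0) -> np.ndarray:
    """Local linear regression with tricube weights in a fixed bp bandwidth.

    For each input position, points within ``span_bp / 2`` bp contribute
    with weight ``(1 - (d/h)^3)^3`` where ``h`` is the half-span; the local
    weighted line is evaluated at that position.  Neighbourhoods with fewer
    than 2 points (or a degenerate design) fall back to the local weighted
    mean.  Endpoints simply see truncated neighbourhoods.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("positions and values must align")
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted")
    h = span_bp / 2.0
    out = np.empty_like(y)
    lo = np.searchsorted(x, x - h, side="left")
    hi = np.searchsorted(x, x + h, side="right")
    for i in range(x.size):
        xs = x[lo[i]:hi[i]]
        ys = y[lo[i]:hi[i]]
        d = np.abs(xs - x[i]) / h
        w = (1.0 - np.minimum(d, 1.0) ** 3) ** 3
        sw = w.sum()
        if xs.size < 2 or sw == 0:
            out[i] = ys.mean() if xs.size else np.nan
            continue
        xm = (w * xs).sum() / sw
        ym = (w * ys).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        if sxx <= 0:
            out[i] = ym
            continue
        beta = (w * (xs - xm) * (ys - ym)).sum() / sxx
        out[i] = ym + beta * (x[i] - xm)
    return out


# ----------------------------------------------------------------- outliers


@dataclass
class OutlierCall:
    interval: tuple[int, int]
    statistic: str
    value: float
    threshold_type: str
    threshold: float
    flag: bool


def percentile_outliers(
    df: pd.DataFrame, statistic: str, q: float = 95.0
) -> list[OutlierCall]:
    """Flag windows above the genome-wide ``q``-th percentile (unmasked only).

    Thresholds use linear-interpolation quantiles of the unmasked
    distribution; flagged windows are strictly above the threshold.
    """
    if q not in (95.0, 99.0) and not 0 < q < 100:
        raise ValueError("q must be a percentage in (0, 100)")
    vals = df[statistic].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("all values are missing")
    thr = float(np.percentile(vals[ok], q))
    out = []
    for row, v in zip(df.itertuples(), vals):
        if np.isnan(v):
            continue
        out.append(
            OutlierCall(
                (int(row.start), int(row.end)), statistic, float(v),
                f"percentile{q:g}", thr, bool(v > thr),
            )
        )
    return out


def tvar_outliers(weights_df: pd.DataFrame, thresholds=(0.55, 0.60)) -> list[OutlierCall]:
    """Raw T_var threshold calls: strict ``>`` at 0.55, ``>=`` at 0.60.

    Any other threshold uses strict ``>``.
    """
    out = []
    for row in weights_df.itertuples():
        for thr in thresholds:
            flag = row.w_var >= thr if thr == 0.60 else row.w_var > thr
            out.append(
                OutlierCall(
                    (int(row.start), int(row.end)), "w_var", float(row.w_var),
                    f"tvar_{thr:g}", thr, bool(flag),
                )
            )
    return out


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    return float(stats.spearmanr(x, y).statistic)
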