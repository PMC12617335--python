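"""F_ST, diversity, loess and outlier calls against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hzgenealogy.scanstats import (
    dxy_window,
    hudson_fst_window,
    loess_smooth,
    percentile_outliers,
    pi_window,
    spearman_rho,
    tvar_outliers,
    wc_fst_site,
    window_scan,
)


def wc_anova_oracle(a1, a2):
    """Textbook two-level ANOVA on haploid 0/1 calls, written independently
    of the implementation: theta = sigma_a^2 / (sigma_a^2 + sigma_w^2)."""
    groups = [np.asarray(a1, float), np.asarray(a2, float)]
    n = np.array([g.size for g in groups])
    N = n.sum()
    r = 2
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = (n * (means - grand) ** 2).sum()
    ss_within = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    msp = ss_between / (r - 1)
    msg = ss_within / (N - r)
    nc = (N - (n**2).sum() / N) / (r - 1)
    s2_a = (msp - msg) / nc
    s2_w = msg
    if s2_a + s2_w == 0:
        return float("nan")
    return s2_a / (s2_a + s2_w)


# -------------------------------------------------------------- per-site WC


def test_wc_matches_anova_oracle_on_random_sites(rng):
    for _ in range(200):
        n1 = int(rng.integers(2, 30))
        n2 = int(rng.integers(2, 30))
        a1 = rng.integers(0, 2, n1)
        a2 = rng.integers(0, 2, n2)
        ours = wc_fst_site(a1, a2)
        oracle = wc_anova_oracle(a1, a2)
        if np.isnan(oracle):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(oracle, abs=1e-12)


def test_wc_fixed_difference_is_one():
    assert wc_fst_site([1] * 10, [0] * 10) == pytest.approx(1.0, abs=1e-12)


def test_wc_equal_frequencies_negative():
    # p1 = p2 = 0.5 with n = 10 each: MSP = 0, n_c = 10, theta = -1/(n_c-1)
    assert wc_fst_site([0, 1] * 5, [1, 0] * 5) == pytest.approx(-1 / 9, abs=1e-12)


def test_wc_monomorphic_site_nan():
    assert np.isnan(wc_fst_site([0] * 5, [0] * 5))


def test_wc_requires_two_alleles_per_pop():
    with pytest.raises(ValueError):
        wc_fst_site([1], [0, 1])


# --------------------------------------------------------- window diversity


def brute_pi(G, L):
    n = G.shape[1]
    tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += int((G[:, i] != G[:, j]).sum())
    return tot / (n * (n - 1) / 2) / L


def brute_dxy(G1, G2, L):
    tot = 0
    for i in range(G1.shape[1]):
        for j in range(G2.shape[1]):
            tot += int((G1[:, i] != G2[:, j]).sum())
    return tot / (G1.shape[1] * G2.shape[1]) / L


def test_pi_and_dxy_match_brute_force(rng):
    for _ in range(20):
        G1 = rng.integers(0, 2, size=(30, 6)).astype(np.int8)
        G2 = rng.integers(0, 2, size=(30, 4)).astype(np.int8)
        assert pi_window(G1, 1_000) == pytest.approx(brute_pi(G1, 1_000), abs=1e-12)
        assert dxy_window(G1, G2, 1_000) == pytest.approx(
            brute_dxy(G1, G2, 1_000), abs=1e-12
        )


def test_hudson_fixed_difference_is_one():
    G1 = np.ones((5, 4), dtype=np.int8)
    G2 = np.zeros((5, 4), dtype=np.int8)
    assert hudson_fst_window(G1, G2) == 1.0


def test_hudson_equal_frequencies_exactly_zero(rng):
    # identical allele frequencies at every site: within het == between het
    G = rng.integers(0, 2, size=(50, 8)).astype(np.int8)
    assert hudson_fst_window(G, G.copy()) == 0.0
    # also with permuted haplotype columns (same frequencies)
    perm = G[:, rng.permutation(8)]
    assert hudson_fst_window(G, perm) == 0.0


def test_hudson_ratio_of_averages_not_average_of_ratios():
    # two heterogeneous sites: per-site F_ST averages differ from the
    # window ratio-of-averages; the implementation pins the latter
    G1 = np.array([[1, 1, 1, 0], [0, 0, 0, 0]], dtype=np.int8)
    G2 = np.array([[0, 0, 0, 0], [1, 0, 0, 0]], dtype=np.int8)
    p1 = G1.mean(axis=1)
    p2 = G2.mean(axis=1)
    hw = p1 * (1 - p1) + p2 * (1 - p2)
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    ratio_of_avg = 1 - hw.sum() / hb.sum()
    avg_of_ratio = np.mean(1 - hw / hb)
    assert hudson_fst_window(G1, G2) == pytest.approx(ratio_of_avg, abs=1e-12)
    assert abs(ratio_of_avg - avg_of_ratio) > 1e-3


def test_hudson_no_between_diversity_nan():
    G = np.zeros((3, 4), dtype=np.int8)
    assert np.isnan(hudson_fst_window(G, G))


def test_pi_scales_with_simulated_theta():
    """Panmictic N gives E[pi] = 2 * (2N) * mu per bp (haploid-pair rate)."""
    from hzgenealogy import DemographyConfig, simdata

    N, mu = 100_000.0, 5.7e-9
    cfg = DemographyConfig.panmictic(
        N=N, n_haplotypes_per_deme=4, chrom_length=400 * 2_000, window_bp=2_000
    )
    cfg.seed = 23
    cfg.mu = mu
    sim = simdata.simulate(cfg)
    G = sim.variants.genotypes
    pi = pi_window(G, cfg.chrom_length)
    expect = 4 * N * mu
    assert pi == pytest.approx(expect, rel=0.1)


# -------------------------------------------------------------- window scan


def test_window_scan_layout_and_masking(small_sim):
    df = window_scan(
        small_sim.variants, small_sim.popmap, "PlaP", "PlaS",
        window_bp=10_000, min_sites=10,
        chrom_length=small_sim.config.chrom_length,
    )
    assert len(df) == small_sim.config.chrom_length // 10_000
    assert (df["end"] - df["start"] == 10_000).all()
    masked = df["masked"]
    assert df.loc[masked, "fst_hudson"].isna().all()
    ok = df.loc[~masked]
    assert (ok["n_sites"] >= 10).all()
    assert ok["pi1"].between(0, 1).all()
    assert (ok["dxy"] >= 0).all()
    assert (ok["fst_hudson"] <= 1).all()


def test_window_scan_counts_every_site(small_sim):
    df = window_scan(
        small_sim.variants, small_sim.popmap, "AveP", "AveS",
        chrom_length=small_sim.config.chrom_length,
    )
    assert df["n_sites"].sum() == small_sim.variants.n_sites


# -------------------------------------------------------------------- loess


def test_loess_exact_on_linear_data():
    x = np.arange(0, 100_000, 1_000, dtype=float)
    y = 3.0 + 2e-4 * x
    np.testing.assert_allclose(loess_smooth(x, y, span_bp=20_000), y, atol=1e-9)


def test_loess_exact_on_constant():
    x = np.arange(50, dtype=float) * 500
    np.testing.assert_allclose(loess_smooth(x, np.full(50, 7.0)), 7.0)


def test_loess_reduces_noise_variance(rng):
    x = np.arange(500, dtype=float) * 1_000
    signal = np.sin(x / 80_000.0)
    noisy = signal + rng.normal(0, 0.5, x.size)
    sm = loess_smooth(x, noisy, span_bp=50_000)
    assert np.mean((sm - signal) ** 2) < 0.25 * np.mean((noisy - signal) ** 2)


def test_loess_rejects_unsorted():
    with pytest.raises(ValueError, match="sorted"):
        loess_smooth([3.0, 1.0, 2.0], [0.0, 0.0, 0.0])


# ----------------------------------------------------------------- outliers


def frame_1_to_100():
    return pd.DataFrame(
        {
            "start": np.arange(100) * 10_000,
            "end": (np.arange(100) + 1) * 10_000,
            "fst_hudson": np.arange(1.0, 101.0),
        }
    )


def test_percentile_95_strictly_above_threshold():
    calls = percentile_outliers(frame_1_to_100(), "fst_hudson", q=95.0)
    # linear-interpolation 95th percentile of 1..100 is 95.05
    assert calls[0].threshold == pytest.approx(95.05)
    flagged = sorted(c.value for c in calls if c.flag)
    assert flagged == [96.0, 97.0, 98.0, 99.0, 100.0]  # ~5% of windows


def test_percentile_99_flags_about_one_percent():
    calls = percentile_outliers(frame_1_to_100(), "fst_hudson", q=99.0)
    flagged = [c.value for c in calls if c.flag]
    assert flagged == [100.0]


def test_percentile_skips_nan_windows():
    df = frame_1_to_100()
    df.loc[10, "fst_hudson"] = np.nan
    calls = percentile_outliers(df, "fst_hudson", q=95.0)
    assert len(calls) == 99


def test_tvar_threshold_semantics():
    df = pd.DataFrame(
        {
            "start": [0, 1, 2, 3],
            "end": [1, 2, 3, 4],
            "w_var": [0.54, 0.55, 0.56, 0.61],
        }
    )
    calls = tvar_outliers(df)
    at_055 = {c.interval[0]: c.flag for c in calls if c.threshold == 0.55}
    at_060 = {c.interval[0]: c.flag for c in calls if c.threshold == 0.60}
    # 0.55 rule is strict: exactly 0.55 is NOT an outlier
    assert at_055 == {0: False, 1: False, 2: True, 3: True}
    # 0.60 rule is inclusive (>=)
    assert at_060 == {0: False, 1: False, 2: False, 3: True}


def test_tvar_exact_060_included():
    df = pd.DataFrame({"start": [0], "end": [1], "w_var": [0.60]})
    calls = {c.threshold: c.flag for c in tvar_outliers(df)}
    assert calls[0.60] is True
    assert calls[0.55] is True  # 0.60 > 0.55


hyp_alleles = st.lists(st.integers(0, 1), min_size=2, max_size=20)


@given(hyp_alleles, hyp_alleles)
@settings(max_examples=200, deadline=None)
def test_wc_invariant_to_pop_order_and_allele_relabelling(a, b):
    """WC theta is symmetric in the two populations and unchanged by
    swapping which allele is called '1'."""
    f = wc_fst_site(a, b)
    swapped = wc_fst_site(b, a)
    relabelled = wc_fst_site([1 - x for x in a], [1 - x for x in b])
    if np.isnan(f):
        assert np.isnan(swapped) and np.isnan(relabelled)
    else:
        assert swapped == pytest.approx(f, abs=1e-12)
        assert relabelled == pytest.approx(f, abs=1e-12)
        assert f <= 1.0 + 1e-12


# ----------------------------------------------------------------- spearman


def test_spearman_matches_rank_pearson(rng):
    x = rng.normal(size=50)
    y = 2 * x + rng.normal(size=50)
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    expect = np.corrcoef(rx, ry)[0, 1]
    assert spearman_rho(x, y) == pytest.approx(expect, abs=1e-12)


def test_spearman_perfect_monotone():
    x = np.arange(10.0)
    assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman_rho(x, -(x**3)) == pytest.approx(-1.0)
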