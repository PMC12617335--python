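# Methods

This document records the model, the parameter defaults, and every
numerical convention the implementation pins down.

## 1. Demographic model

The simulator (`hzgenealogy.simdata`) draws one independent structured
coalescent tree per genomic window for four demes: `PlaP`, `PlaS` (zone
Planoles) and `AveP`, `AveS` (zone Avellanet), where `P` is variety
*pseudomajus* and `S` is variety *striatum*. Backwards in time:

| epoch (generations ago) | state |
|---|---|
| `[0, T_sc)` | four demes; within each zone, lineages migrate between the two varieties' demes with backwards per-lineage probabilities `m12` (P→S) and `m21` (S→P); optional exponential growth (`growth1`, `growth2`) since `T_sc` |
| `[T_sc, T_col)` | four demes, no migration (the varieties are in contact only since `T_sc`) |
| `[T_col, T_split_var)` | the two zones of each variety merge: two variety demes of sizes `N1`, `N2` |
| `[T_split_var, ∞)` | a single ancestral deme of size `N_anc` |

Coalescence within a deme of diploid size `N` occurs at rate
`k(k−1)/2 × 1/(2N)` for `k` lineages. Waiting times under growth use the
closed-form inversion of the inhomogeneous exponential rate.

**Barrier loci** `(interval, b)` multiply both migration rates by `(1−b)`
for windows inside the interval; `b = 1` is a complete barrier.
**Sweep loci** `(interval, variety, T_sweep, factor)` open a bottleneck
epoch at `T_sweep` during which the affected variety's deme sizes are
multiplied by `factor`, lasting until that variety's lineages in the
window have coalesced to one, or until a cap of
`20 × 2 × N_deme × factor` generations — an instantaneous-sweep
approximation by drastic size reduction rather than a frequency
trajectory.

Mutations are dropped on branches under the infinite-sites model:
per-window Poisson counts with mean `mu × span × total branch length`,
positions drawn uniformly without replacement, derived alleles assigned to
the leaves below the mutated branch. Haplotypes are named
`<pop><k>_a` / `<pop><k>_b` and written to VCF as phased diploid samples
`<pop><k>` with `a|b` genotypes.

### Defaults (the study conditions)

- `n_haplotypes_per_deme = 10` (5 diploids per population)
- `N_anc = N1 = N2 = N_deme = 400,000` diploids — chosen so neutral
  diversity `π = 4Nμ ≈ 0.009` matches the observed genome-wide θ with the
  mutation rate below
- `T_split_var = 600,000`, `T_col = 150,000`, `T_sc = 50,000` generations
- `m12 = m21 = 2e-5` per lineage per generation
- `mu = 5.7e-9` per bp per generation
- `window_bp = 2,000` (one marginal tree per 2-kbp window)

These defaults were frozen before the test suite was written and are never
tuned toward test outcomes. `DemographyConfig.panmictic(N)` collapses all
epochs (split times 1, 2, 3; no migration) for null calibrations.

### What the generator emulates — and what it does not

Emulated: secondary contact after allopatric divergence, asymmetric
introgression, localized barriers, variety-specific sweeps, exponential
growth since contact. **Not** emulated: linkage between windows (no ARG;
each window's tree is independent, so landscape autocorrelation comes only
from shared parameters, not shared ancestry), selection dynamics
(sweeps are bottleneck epochs), gene conversion, missing data or genotype
error (output is fully called and phased).

## 2. Topology weighting

For four populations there are three unrooted quartet topologies:
`T_geo` pairs the two same-zone population pairs
`(AveS,AveP),(PlaS,PlaP)`; `T_var` pairs same-variety populations
`(AveS,PlaS),(AveP,PlaP)`; `T_alt` is the remainder. A one-per-population
quartet `{a, b, c, d}` matches pairing `ab|cd` iff the subtree below
`MRCA(a,b)` contains neither `c` nor `d`, **or** symmetrically for
`(c,d)` — a criterion invariant to the root position, verified by
re-rooting tests. Quartets resolved as none of the three (possible only at
polytomies) accumulate in a residual `u`, so
`w_geo + w_var + w_alt + u = 1` always.

Exact weighting enumerates all `n_A·n_B·n_C·n_D` quartets, vectorised via
per-node descendant masks and an all-pairs MRCA matrix, and is used
automatically up to 1e7 quartets; beyond that, `n = 10,000` quartets are
sampled **with replacement** from independent per-tree seeded streams
(binomial standard error `sqrt(w(1−w)/n)`, confirmed unbiased against the
exact values).

## 3. Ternary representation and asymmetry

Weight triples are renormalised over classified mass (`u` excluded;
`u = 1` trees dropped) and mapped to the unit triangle with `GEO` at the
apex `(0.5, √3/2)`, `VAR` at `(1, 0)`, `ALT` at `(0, 0)`. The simplex is
binned on a lattice of edge width `g = 0.02` by default (the finest grid
that keeps ≥ tens of expected points per bin at genome scale); bins are
the `K²` up/down triangles, mirrored by swapping the VAR and ALT indices.
Global asymmetry is `D_lr = (n_right − n_left)/(n_right + n_left)` over
trees off the `w_var = w_alt` axis (axis ties excluded); per mirrored bin
pair, a two-sided binomial test of p = 0.5 is BH-adjusted across pairs.

## 4. Genome-scan statistics

- **Weir–Cockerham F_ST (per site)**: two-population variance-components θ
  treating phased haplotypes as haploid samples (no within-individual
  heterozygosity term), `θ = (MSP − MSG)/(MSP + (n_c − 1)MSG)`. Undefined
  (monomorphic, 0/0) sites return NaN and are excluded from window means,
  with the count reported. Negative estimates are reported, not clamped.
- **π / d_xy (windowed)**: mean pairwise differences — π with the
  `n(n−1)/2` pair denominator, d_xy over all cross pairs — divided by the
  callable window length in bp (10-kbp non-overlapping windows, masked
  under `min_sites = 10`).
- **Hudson F_ST (windowed)**: `1 − H_w / H_b` as a **ratio of window
  sums**, with `H_w = Σ p₁(1−p₁) + p₂(1−p₂)` (mean of the two populations)
  and `H_b = Σ p₁(1−p₂) + p₂(1−p₁)`. The frequency (heterozygosity) form
  is used rather than the sample-corrected pairwise form so that the
  estimator is exactly 0 when the two populations share all allele
  frequencies and exactly 1 at fixed differences; NaN when `H_b = 0`.
- **Loess**: local weighted linear regression with tricube weights over a
  fixed ±`span_bp/2` neighbourhood (default span 50 kbp), evaluated at
  each input position; degenerate neighbourhoods fall back to the weighted
  mean.
- **Outliers**: percentile thresholds use linear-interpolation quantiles
  of the unmasked distribution with a strict `>` flag; raw `T_var`
  thresholds are strict `>` at 0.55 and inclusive `≥` at 0.60 — the two
  printed conventions, preserved exactly.
- **Spearman ρ**: Pearson correlation of mid-ranks (`scipy.stats.spearmanr`).

## 5. Window trees and neighbour joining

Windows are consecutive blocks of exactly 50 SNPs (trailing remainder
dropped); distances are raw Hamming mismatch counts between phased
haplotypes (scaling does not affect the NJ topology). Saitou–Nei
neighbour joining is used with deterministic lowest-index tie-breaking;
negative branch lengths are clamped to zero (count logged). The unrooted
result is midpoint-rooted for storage; node ages are defined as the
maximum path length to a descendant leaf, with original branch lengths
kept separately so newick round-trips are exact. NJ is provably consistent
on additive matrices; the suite verifies 100/100 topology recovery from
random 8-taxon trees and agreement with an independent implementation.

## 6. TMRCA summaries

Per tree, pairwise TMRCAs are summarised as the median over three pair
sets: within variety P (all `PlaP` + `AveP` haplotypes), within variety S,
and between varieties (all cross pairs). Medians use numpy's midpoint
convention for even pair counts. Units are **haplotypes** by default;
`diploid=True` first averages each individual's 2×2 haplotype block.
Locus-versus-flank contrasts assign each tree by its interval midpoint
(half-open `[start, end)` locus). The weight–TMRCA association is Spearman
ρ with a seeded permutation p-value, `(exceedances + 1)/(n_perm + 1)`.

## 7. Reproducibility conventions

- All randomness flows through `numpy.random.Generator(PCG64)`; per-window
  streams are derived as `SeedSequence([seed, window_index])` (and a
  distinct constant for mutations), so window `w` is identical no matter
  how many windows are simulated.
- SNPs are assigned to marginal trees by half-open interval
  `[start, end)` via binary search; out-of-range SNPs are counted in an
  explicit `unassigned` bucket, never silently dropped.
- VCF positions are 1-based on disk, 0-based in memory.
- Tolerances: exact-weight identities at 1e-12; oracle comparisons at
  1e-12–1e-15; stochastic checks at 3 standard errors with fixed seeds.
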