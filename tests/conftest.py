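"""Shared fixtures: synthetic replicates generated once per session."""

import numpy as np
import pytest

from hzgenealogy import DemographyConfig, simdata
from hzgenealogy.treeio import PopulationMap, parse_newick
from hzgenealogy.twisst import weight_sequence


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240917))


@pytest.fixture(scope="session")
def popmap4():
    """One haplotype per population."""
    return PopulationMap(
        {"AveP0_a": "AveP", "AveS0_a": "AveS", "PlaP0_a": "PlaP", "PlaS0_a": "PlaS"}
    )


@pytest.fixture(scope="session")
def popmap8():
    """Two haplotypes per population (for small enumerations)."""
    return PopulationMap.default(2)


@pytest.fixture(scope="session")
def sorted_tree():
    """Fully sorted, zone-clustered tree: populations reciprocally
    monophyletic, same-zone populations sisters (2 haplotypes each)."""
    nwk = (
        "((((AveS0_a:1,AveS0_b:1):1,(AveS1_a:1,AveS1_b:1):1):2,"
        "((AveP0_a:1,AveP0_b:1):1,(AveP1_a:1,AveP1_b:1):1):2):3,"
        "(((PlaS0_a:1,PlaS0_b:1):1,(PlaS1_a:1,PlaS1_b:1):1):2,"
        "((PlaP0_a:1,PlaP0_b:1):1,(PlaP1_a:1,PlaP1_b:1):1):2):3);"
    )
    return parse_newick(nwk)


@pytest.fixture(scope="session")
def popmap_sorted():
    return PopulationMap.default(4)


@pytest.fixture(scope="session")
def caterpillar_tree():
    """Fixed mixed caterpillar with 2 haplotypes per population: group
    membership deliberately scrambled so all three topologies get weight."""
    nwk = (
        "(AveP0_a:8,(PlaS0_a:7,(AveS0_a:6,(PlaP0_a:5,(AveP0_b:4,"
        "(PlaP0_b:3,(AveS0_b:2,PlaS0_b:1):1):1):1):1):1):1);"
    )
    return parse_newick(nwk)


@pytest.fixture(scope="session")
def small_sim():
    """Default secondary-contact replicate: 30 windows with genotypes."""
    cfg = DemographyConfig(chrom_length=60_000, window_bp=2_000, seed=101)
    return simdata.simulate(cfg)


@pytest.fixture(scope="session")
def panmictic_run():
    """2,000 effectively panmictic windows plus their exact topology weights
    — the symmetric neutral null shared by several calibration tests."""
    cfg = DemographyConfig.panmictic(
        N=400_000.0, chrom_length=2_000 * 2_000, window_bp=2_000, seed=202
    )
    sim = simdata.simulate_tree_sequence(cfg)
    weights = weight_sequence(sim.trees, sim.popmap, method="exact")
    return sim, weights


@pytest.fixture(scope="session")
def barrier_sweep_run():
    """600 windows; the middle 200 carry a full barrier (b = 1) plus a recent
    sweep in variety striatum — the parameter-recovery scenario."""
    n, w = 600, 2_000
    locus = (200 * w, 400 * w)
    cfg = DemographyConfig(
        chrom_length=n * w,
        window_bp=w,
        seed=303,
        barrier_loci=[(locus, 1.0)],
        sweep_loci=[(locus, "striatum", 1_000.0, 0.01)],
    )
    sim = simdata.simulate_tree_sequence(cfg)
    weights = weight_sequence(sim.trees, sim.popmap, method="exact")
    return sim, weights, locus
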