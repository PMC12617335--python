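"""Topology weighting: enumeration oracle, invariances, sampler calibration."""

import itertools

import numpy as np
import pytest

from hzgenealogy.treeio import PopulationMap, TreeSequenceTable, parse_newick
from hzgenealogy.trees import NULL, GenomeTree, random_coalescent_tree
from hzgenealogy.twisst import (
    classify_quartet,
    weight_sequence,
    weight_tree_exact,
    weight_tree_sampled,
)

POP_ORDER = ("AveP", "AveS", "PlaP", "PlaS")


def enumeration_oracle(tree, popmap):
    """Brute force: classify every one-per-population quartet individually."""
    pools = [
        [h for h in tree.leaf_labels if popmap.haplotype_to_pop.get(h) == p]
        for p in POP_ORDER
    ]
    counts = {"geo": 0, "var": 0, "alt": 0, "unresolved": 0}
    total = 0
    for combo in itertools.product(*pools):
        counts[classify_quartet(tree, dict(zip(POP_ORDER, combo)))] += 1
        total += 1
    return {k: v / total for k, v in counts.items()}


def random_population_tree(rng, n_per_pop=2):
    labels = [f"{p}{i // 2}_{'ab'[i % 2]}" for p in POP_ORDER for i in range(n_per_pop)]
    return random_coalescent_tree(labels, rng), PopulationMap.default(n_per_pop)


# ------------------------------------------------------------ classification


def test_classify_quartet_geo():
    t = parse_newick("((PlaP0_a:1,PlaS0_a:1):1,(AveP0_a:1,AveS0_a:1):1);")
    assert classify_quartet(t, ["AveP0_a", "AveS0_a", "PlaP0_a", "PlaS0_a"]) == "geo"


def test_classify_quartet_var():
    t = parse_newick("((PlaP0_a:1,AveP0_a:1):1,(PlaS0_a:1,AveS0_a:1):1);")
    assert classify_quartet(t, ["AveP0_a", "AveS0_a", "PlaP0_a", "PlaS0_a"]) == "var"


def test_classify_quartet_star_unresolved():
    t = parse_newick("(AveP0_a:1,AveS0_a:1,PlaP0_a:1,PlaS0_a:1);")
    assert (
        classify_quartet(t, ["AveP0_a", "AveS0_a", "PlaP0_a", "PlaS0_a"])
        == "unresolved"
    )


def test_classify_quartet_missing_leaf_raises():
    t = parse_newick("((PlaP0_a:1,PlaS0_a:1):1,(AveP0_a:1,AveS0_a:1):1);")
    with pytest.raises(KeyError):
        classify_quartet(t, ["AveP0_a", "AveS0_a", "PlaP0_a", "nope"])


# ------------------------------------------------------------------- exact


def test_sorted_zone_clustered_tree_weights(sorted_tree, popmap_sorted):
    """The fully sorted, zone-clustered tree carries all weight on the
    geography topology: (1, 0, 0)."""
    w = weight_tree_exact(sorted_tree, popmap_sorted)
    assert (w.w_geo, w.w_var, w.w_alt, w.u) == (1.0, 0.0, 0.0, 0.0)
    assert w.n_evaluated == 4**4


def test_variety_paired_single_haplotypes(popmap4):
    t = parse_newick("((PlaP0_a:1,AveP0_a:1):1,(PlaS0_a:1,AveS0_a:1):1);")
    w = weight_tree_exact(t, popmap4)
    assert (w.w_geo, w.w_var, w.w_alt) == (0.0, 1.0, 0.0)


def test_exact_equals_enumeration_on_caterpillar(caterpillar_tree, popmap8):
    w = weight_tree_exact(caterpillar_tree, popmap8)
    oracle = enumeration_oracle(caterpillar_tree, popmap8)
    assert w.w_geo == pytest.approx(oracle["geo"], abs=1e-15)
    assert w.w_var == pytest.approx(oracle["var"], abs=1e-15)
    assert w.w_alt == pytest.approx(oracle["alt"], abs=1e-15)
    assert w.n_evaluated == 16


def test_exact_equals_enumeration_on_random_trees(rng):
    for _ in range(15):
        tree, pm = random_population_tree(rng)
        w = weight_tree_exact(tree, pm)
        oracle = enumeration_oracle(tree, pm)
        for name, val in (("geo", w.w_geo), ("var", w.w_var), ("alt", w.w_alt)):
            assert val == pytest.approx(oracle[name], abs=1e-15)


def test_weights_sum_to_one_bifurcating(rng):
    for _ in range(50):
        tree, pm = random_population_tree(rng, n_per_pop=4)
        w = weight_tree_exact(tree, pm)
        assert w.u == 0.0
        assert w.w_geo + w.w_var + w.w_alt == pytest.approx(1.0, abs=1e-12)


def collapse_random_edges(tree, rng, k=3):
    """Create polytomies by merging k random internal nodes into parents."""
    parent = tree.parent.copy()
    internal = [
        v for v in range(tree.n_nodes)
        if tree.children[v] and parent[v] != NULL
    ]
    drop = list(rng.choice(internal, size=min(k, len(internal)), replace=False))
    keep = [v for v in range(tree.n_nodes) if v not in drop]
    remap = {}
    for v in drop:
        p = int(parent[v])
        while p in drop:
            p = int(parent[p])
        remap[v] = p
    new_index = {v: i for i, v in enumerate(keep)}
    new_parent, new_time, new_labels = [], [], []
    for v in keep:
        p = int(parent[v])
        while p in remap:
            p = remap[p]
        new_parent.append(new_index[p] if p != NULL else NULL)
        new_time.append(tree.time[v])
        new_labels.append(tree.labels[v])
    return GenomeTree(tree.interval, new_parent, new_time, new_labels)


def test_polytomy_mass_kept_as_residual(rng):
    """With polytomies, w_geo + w_var + w_alt + u = 1 and u > 0 is possible."""
    saw_unresolved = False
    for _ in range(30):
        tree, pm = random_population_tree(rng, n_per_pop=3)
        poly = collapse_random_edges(tree, rng, k=4)
        w = weight_tree_exact(poly, pm)
        assert w.w_geo + w.w_var + w.w_alt + w.u == pytest.approx(1.0, abs=1e-12)
        oracle = enumeration_oracle(poly, pm)
        assert w.u == pytest.approx(oracle["unresolved"], abs=1e-15)
        saw_unresolved |= w.u > 0
    assert saw_unresolved


def test_exact_invariant_to_relabelling_within_population(rng):
    tree, pm = random_population_tree(rng, n_per_pop=3)
    w1 = weight_tree_exact(tree, pm)
    # swap two AveP haplotype labels
    swapped = {"AveP0_a": "AveP1_a", "AveP1_a": "AveP0_a"}
    labels = [swapped.get(l, l) if l else None for l in tree.labels]
    tree2 = GenomeTree(tree.interval, tree.parent, tree.time, labels)
    w2 = weight_tree_exact(tree2, pm)
    assert (w1.w_geo, w1.w_var, w1.w_alt) == (w2.w_geo, w2.w_var, w2.w_alt)


def reroot_with_dendropy(tree, rng):
    """Re-root the same unrooted shape on a random internal edge."""
    import dendropy

    from hzgenealogy.treeio import parse_newick, write_newick

    dt = dendropy.Tree.get(
        data=write_newick(tree), schema="newick", preserve_underscores=True
    )
    edges = [
        e for e in dt.preorder_edge_iter()
        if e.head_node.parent_node is not None and not e.head_node.is_leaf()
    ]
    e = edges[int(rng.integers(len(edges)))]
    dt.reroot_at_edge(e, update_bipartitions=False, length1=e.length / 2, length2=e.length / 2)
    return parse_newick(dt.as_string(schema="newick").strip())


def test_unrooted_classification_invariant_to_rerooting(rng):
    for _ in range(20):
        tree, pm = random_population_tree(rng, n_per_pop=2)
        tree2 = reroot_with_dendropy(tree, rng)
        w1 = weight_tree_exact(tree, pm)
        w2 = weight_tree_exact(tree2, pm)
        assert (w1.w_geo, w1.w_var, w1.w_alt) == (w2.w_geo, w2.w_var, w2.w_alt)


# ------------------------------------------------------------------ sampled


def test_sampled_exact_on_pure_tree(sorted_tree, popmap_sorted):
    w = weight_tree_sampled(sorted_tree, popmap_sorted, n_subtrees=500, seed=3)
    assert (w.w_geo, w.w_var, w.w_alt) == (1.0, 0.0, 0.0)


def test_sampler_is_unbiased(caterpillar_tree, popmap8):
    """Mean sampled weight over 200 seeds within 3*SE/sqrt(200) of exact."""
    exact = weight_tree_exact(caterpillar_tree, popmap8)
    n = 2_000
    samples = np.array(
        [
            [w.w_geo, w.w_var, w.w_alt]
            for w in (
                weight_tree_sampled(caterpillar_tree, popmap8, n_subtrees=n, seed=s)
                for s in range(200)
            )
        ]
    )
    for k, we in enumerate((exact.w_geo, exact.w_var, exact.w_alt)):
        se = np.sqrt(we * (1 - we) / n) / np.sqrt(200)
        assert abs(samples[:, k].mean() - we) < 3 * se


def test_sampled_reproducible_given_seed(caterpillar_tree, popmap8):
    a = weight_tree_sampled(caterpillar_tree, popmap8, 1_000, seed=11)
    b = weight_tree_sampled(caterpillar_tree, popmap8, 1_000, seed=11)
    assert a == b


def test_sampled_rejects_nonpositive_n(caterpillar_tree, popmap8):
    with pytest.raises(ValueError):
        weight_tree_sampled(caterpillar_tree, popmap8, 0, seed=1)


# ----------------------------------------------------------------- sequence


def test_weight_sequence_empty():
    table = TreeSequenceTable([], chrom="chr1")
    pm = PopulationMap.default(2)
    assert weight_sequence(table, pm) == []


def test_weight_sequence_missing_population_raises(rng):
    tree = random_coalescent_tree(["PlaP0_a", "PlaP0_b", "PlaS0_a", "PlaS0_b"], rng)
    pm = PopulationMap.default(1)
    with pytest.raises(ValueError):
        weight_sequence(TreeSequenceTable([tree]), pm, method="exact")
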