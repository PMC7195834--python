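"""Dispersal-vicariance reconstruction: oracle equivalence and invariants."""

import numpy as np
import pytest

from vicarange.diva import (
    AreaSystem,
    diva_exhaustive,
    diva_optimize,
    maxareas_sensitivity,
    sdiva_frequencies,
)
from vicarange.experiments import diva_oracle_agreement, random_coalescent_newick
from vicarange.trees import read_tree


def _sets(rec, tips):
    return sorted(map(sorted, rec.node_by_tips(tips).optimal_sets))


def test_single_area_history_costs_zero():
    tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
    tips = {t: frozenset("a") for t in "ABCD"}
    rec = diva_optimize(tree, tips, maxareas=1)
    assert rec.total_cost == 0
    for nr in rec.nodes.values():
        assert nr.optimal_sets == [frozenset("a")]
        assert abs(sum(nr.frequencies) - 1) < 1e-9


def test_cherry_vicariance_is_free():
    tree = read_tree("(A:1,B:1);")
    areas = AreaSystem(["a", "b"], [("a", "b")])
    rec = diva_optimize(tree, {"A": frozenset("a"), "B": frozenset("b")},
                        maxareas=2, areas=areas)
    assert rec.total_cost == 0
    assert rec.node_by_tips(["A", "B"]).optimal_sets == [frozenset("ab")]


def test_dp_equals_exhaustive_on_random_instances():
    res = diva_oracle_agreement(n_instances=120, seed=5)
    assert res["agreement"] == 1.0


def test_cost_non_increasing_in_maxareas(rng):
    areas = AreaSystem(list("abcd"), [])
    subsets = [frozenset(s) for s in ("a", "b", "c", "d", "ab", "cd", "ad")]
    for _ in range(20):
        tree = read_tree(random_coalescent_newick(list("PQRST"), rng))
        tips = {t: subsets[rng.integers(len(subsets))] for t in "PQRST"}
        costs = [
            diva_optimize(tree, tips, k, areas).total_cost for k in (2, 3, 4)
        ]
        assert costs[0] >= costs[1] >= costs[2]


def test_area_relabeling_equivariance(rng):
    tree = read_tree(random_coalescent_newick(list("WXYZ"), rng))
    tips = {"W": frozenset("a"), "X": frozenset("b"),
            "Y": frozenset(["a", "c"]), "Z": frozenset("c")}
    rec1 = diva_optimize(tree, tips, 2, AreaSystem(list("abc"), []))
    perm = {"a": "c", "b": "a", "c": "b"}
    tips2 = {t: frozenset(perm[x] for x in s) for t, s in tips.items()}
    rec2 = diva_optimize(tree, tips2, 2, AreaSystem(list("abc"), []))
    assert rec1.total_cost == rec2.total_cost
    for clade, nr in rec1.nodes.items():
        mapped = sorted(
            sorted(perm[x] for x in s) for s in nr.optimal_sets
        )
        assert mapped == sorted(map(sorted, rec2.nodes[clade].optimal_sets))


def test_true_root_recovered_without_extinction():
    """With zero extinction and sparse dispersal the simulated root range is
    among the cost-optimal root sets in >= 95% of replicates."""
    from vicarange.simulate import (
        SimulationConfig,
        default_area_system,
        simulate_biogeography,
        simulate_dated_tree,
    )

    hits = reps = 0
    rng = np.random.default_rng(17)
    for _ in range(200):
        cfg = SimulationConfig(n_species=6, dispersal_rate=0.05,
                               extinction_rate=0.0, area_count=5,
                               seed=int(rng.integers(2**31 - 1)))
        areas = default_area_system(5)
        rep_rng = np.random.default_rng(cfg.seed)
        tree = simulate_dated_tree(cfg, rep_rng)
        hist = simulate_biogeography(tree, areas, cfg, rep_rng)
        rec = diva_optimize(tree, hist.tip_areas, len(areas.labels), areas)
        root_clade = frozenset(hist.tip_areas)
        hits += hist.root_set in rec.nodes[root_clade].optimal_sets
        reps += 1
    assert hits / reps >= 0.95


def test_wide_ancestral_range_recovered():
    """A clade seeded from a wide range leaves the full range among the
    optimal root reconstructions."""
    tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
    tips = {"A": frozenset("a"), "B": frozenset("b"),
            "C": frozenset("c"), "D": frozenset("d")}
    rec = diva_optimize(tree, tips, 4, AreaSystem(list("abcd"), []))
    assert frozenset("abcd") in rec.node_by_tips(list("ABCD")).optimal_sets
    assert rec.total_cost == 0


def test_errors():
    tree = read_tree("(A:1,B:1);")
    with pytest.raises(ValueError):
        diva_optimize(tree, {"A": frozenset("a")}, 1)
    with pytest.raises(ValueError):
        diva_optimize(tree, {"A": frozenset("ab"), "B": frozenset("a")}, 1,
                      AreaSystem(list("ab"), []))


# ------------------------------------------------------------------- S-DIVA


def test_single_tree_sdiva_equals_uniform():
    tree = read_tree("((A:1,B:1):1,C:2);")
    tips = {"A": frozenset("a"), "B": frozenset("b"), "C": frozenset("c")}
    single = diva_optimize(tree, tips, 2, AreaSystem(list("abc"), []))
    multi = sdiva_frequencies([tree], tips, 2, AreaSystem(list("abc"), []))
    for clade, nr in single.nodes.items():
        m = multi.nodes[clade]
        assert sorted(map(sorted, nr.optimal_sets)) == sorted(map(sorted, m.optimal_sets))
        assert np.allclose(sorted(nr.frequencies), sorted(m.frequencies))
        assert m.clade_support == 1.0


def test_duplicated_trees_idempotent():
    tree = read_tree("((A:1,B:1):1,C:2);")
    tips = {"A": frozenset("a"), "B": frozenset("b"), "C": frozenset("c")}
    one = sdiva_frequencies([tree], tips, 2)
    two = sdiva_frequencies([tree, tree], tips, 2)
    for clade in one.nodes:
        assert one.nodes[clade].frequencies == two.nodes[clade].frequencies
        assert two.nodes[clade].clade_support == 1.0


def test_unstable_clade_support_scales_frequencies():
    """Hand tally: a clade in 6/10 trees gets support 0.6 and its
    support-weighted set frequencies sum to 0.6."""
    t1 = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = read_tree("(((A:1,C:1):0.5,B:1.5):0.5,D:2);")
    tips = {"A": frozenset("a"), "B": frozenset("b"),
            "C": frozenset("c"), "D": frozenset("d")}
    rec = sdiva_frequencies([t1] * 6 + [t2] * 4, tips, 2)
    ab = rec.nodes[frozenset(["A", "B"])]
    assert ab.clade_support == pytest.approx(0.6)
    assert sum(ab.weighted_frequencies()) == pytest.approx(0.6)
    assert sum(ab.frequencies) == pytest.approx(1.0)
    # within-clade frequencies equal the single-tree uniform distribution
    single = diva_optimize(t1, tips, 2)
    assert sorted(map(sorted, ab.optimal_sets)) == sorted(
        map(sorted, single.nodes[frozenset(["A", "B"])].optimal_sets)
    )


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        sdiva_frequencies([], {}, 2)


# ------------------------------------------------------- maxareas sensitivity


def test_sensitivity_agreement_on_single_area_history():
    tree = read_tree("((A:1,B:1):1,C:2);")
    tips = {t: frozenset("a") for t in "ABC"}
    rep = maxareas_sensitivity(tree, tips, [1, 2, 3], AreaSystem(list("abc"), []))
    assert rep.all_agree()
    assert rep.rejected == {}


def test_sensitivity_flags_capped_root():
    """maxareas=2 forbids the free three-area root; the report flags it."""
    tree = read_tree("((A:1,B:1):1,C:2);")
    tips = {"A": frozenset("a"), "B": frozenset("b"), "C": frozenset("c")}
    areas = AreaSystem(list("abc"), [])
    rep = maxareas_sensitivity(tree, tips, [2, 3], areas)
    root = frozenset("ABC")
    assert not rep.agree[root]
    assert frozenset("abc") in rep.alternatives[root][3]
    assert all(len(s) <= 2 for s in rep.alternatives[root][2])


def test_sensitivity_matches_pairwise_diff_of_runs(rng):
    areas = AreaSystem(list("abc"), [])
    subsets = [frozenset(s) for s in ("a", "b", "c", "ab", "bc")]
    for _ in range(10):
        tree = read_tree(random_coalescent_newick(list("WXYZ"), rng))
        tips = {t: subsets[rng.integers(len(subsets))] for t in "WXYZ"}
        rep = maxareas_sensitivity(tree, tips, [2, 3], areas)
        r2 = diva_optimize(tree, tips, 2, areas)
        r3 = diva_optimize(tree, tips, 3, areas)
        for clade in r2.nodes:
            same = sorted(map(sorted, r2.nodes[clade].optimal_sets)) == sorted(
                map(sorted, r3.nodes[clade].optimal_sets)
            )
            assert rep.agree[clade] == same


def test_sensitivity_rejects_settings_below_tip_sets():
    tree = read_tree("(A:1,B:1);")
    tips = {"A": frozenset("ab"), "B": frozenset("c")}
    rep = maxareas_sensitivity(tree, tips, [1, 2, 3], AreaSystem(list("abc"), []))
    assert 1 in rep.rejected
    assert rep.settings == [2, 3]
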