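"""Generator tests: conditioning, determinism, and rate calibration."""

import numpy as np
import pytest

from vicarange.likelihood import hky_distance_expectation
from vicarange.simulate import (
    SimulationConfig,
    default_area_system,
    expand_haplotypes,
    simulate_alignment,
    simulate_biogeography,
    simulate_dated_tree,
    simulate_dataset,
)
from vicarange.trees import IndexedTree, is_ultrametric, tree_to_newick


def test_two_species_gives_a_cherry():
    cfg = SimulationConfig(n_species=2, seed=1)
    tree = simulate_dated_tree(cfg)
    tips = tree.leaf_nodes()
    assert len(tips) == 2
    assert len(tree.internal_nodes()) == 1
    assert is_ultrametric(tree, tol=1e-9)


def test_seed_determinism_tree():
    cfg = SimulationConfig(n_species=10, birth_rate=0.3, death_rate=0.1, seed=1)
    n1 = tree_to_newick(simulate_dated_tree(cfg))
    n2 = tree_to_newick(simulate_dated_tree(cfg))
    assert n1 == n2


def test_tip_count_and_ultrametricity_with_extinction():
    for seed in range(5):
        cfg = SimulationConfig(n_species=8, birth_rate=0.4, death_rate=0.15,
                               seed=seed)
        tree = simulate_dated_tree(cfg)
        assert len(tree.leaf_nodes()) == 8
        it = IndexedTree(tree)
        ages = it.ages_from_edges()
        # max-min root-to-tip path difference below 1e-9 Ma
        assert np.abs(ages[: it.n_tips]).max() < 1e-9
        assert ages[it.root] <= cfg.root_age_bound


def test_nonviable_parameters_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_species=1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(birth_rate=0.1, death_rate=0.2).validate()


def _independent_yule_root_ages(n_reps, n, lam, rng):
    """Per-lineage Gillespie oracle with the same stopping rule
    (uniform stop time while the extant count equals n)."""
    out = []
    for _ in range(n_reps):
        t, k = 0.0, 2
        while k < n:
            # next event = min of k independent Exp(lam) clocks
            t += rng.exponential(1.0 / lam / k)
            k += 1
        t += rng.uniform(0.0, rng.exponential(1.0 / (lam * n)))
        out.append(t)
    return np.array(out)


def test_yule_mean_root_age_matches_oracle():
    lam, n, reps = 0.3, 10, 300
    rng = np.random.default_rng(42)
    cfg = SimulationConfig(n_species=n, birth_rate=lam, death_rate=0.0,
                           root_age_bound=1e9, seed=0)
    sim_ages = []
    for _ in range(reps):
        tree = simulate_dated_tree(cfg, rng)
        it = IndexedTree(tree)
        sim_ages.append(it.ages_from_edges()[it.root])
    sim_ages = np.array(sim_ages)
    oracle = _independent_yule_root_ages(reps, n, lam, np.random.default_rng(7))
    se = np.sqrt(sim_ages.var() / reps + oracle.var() / reps)
    assert abs(sim_ages.mean() - oracle.mean()) < 3 * se


# ---------------------------------------------------------------- biogeography


def test_no_event_history_keeps_root_area():
    cfg = SimulationConfig(n_species=6, dispersal_rate=0.0, extinction_rate=0.0,
                           seed=2)
    areas = default_area_system(4)
    tree = simulate_dated_tree(cfg)
    hist = simulate_biogeography(tree, areas, cfg, root_set=frozenset(["a"]))
    assert all(s == frozenset(["a"]) for s in hist.node_areas.values())
    assert all(e.kind == "duplication" for e in hist.events)


def test_biogeography_seed_determinism():
    cfg = SimulationConfig(n_species=6, seed=3)
    areas = default_area_system(5)
    tree = simulate_dated_tree(cfg)
    h1 = simulate_biogeography(tree, areas, cfg)
    h2 = simulate_biogeography(tree, areas, cfg)
    assert [e.__dict__ for e in h1.events] == [e.__dict__ for e in h2.events]


def test_disconnected_adjacency_rejected():
    from vicarange.diva import AreaSystem

    cfg = SimulationConfig(seed=1)
    areas = AreaSystem(["a", "b", "c"], [("a", "b")])
    tree = simulate_dated_tree(SimulationConfig(n_species=4, seed=1))
    with pytest.raises(ValueError):
        simulate_biogeography(tree, areas, cfg)


def _replay(history):
    """Replay oracle: recompute every tip set from the event list alone."""
    split_at = {e.node: e for e in history.events
                if e.kind in ("vicariance", "duplication")}
    tips = {}

    def walk(node, inherited):
        lbl = node.taxon.label if node.is_leaf() else node.label
        s = set(inherited)
        branch = [e for e in history.events if e.node == lbl
                  and e.kind in ("dispersal", "extinction")]
        branch.sort(key=lambda e: -e.time)
        for e in branch:
            if e.kind == "dispersal":
                assert e.areas[0] not in s
                s.add(e.areas[0])
            else:
                assert e.areas[0] in s
                s.discard(e.areas[0])
            assert s, "range never empties"
        if node.is_leaf():
            tips[lbl] = frozenset(s)
            return
        ev = split_at[lbl]
        if ev.kind == "vicariance":
            sides = [set(ev.inherited[c.taxon.label if c.is_leaf() else c.label])
                     for c in node.child_nodes()]
            assert not (sides[0] & sides[1]) and (sides[0] | sides[1]) == s
        for child in node.child_nodes():
            clbl = child.taxon.label if child.is_leaf() else child.label
            walk(child, ev.inherited[clbl])

    root = history.tree.seed_node
    root_lbl = root.label
    # no branch above the root: its recorded set is the starting state
    assert history.node_areas[root_lbl] == history.root_set
    ev = split_at[root_lbl]
    for child in root.child_nodes():
        clbl = child.taxon.label if child.is_leaf() else child.label
        walk(child, ev.inherited[clbl])
    return tips


def test_tip_areas_match_event_replay():
    for seed in range(5):
        cfg = SimulationConfig(n_species=8, dispersal_rate=0.2,
                               extinction_rate=0.3, seed=seed)
        areas = default_area_system(6)
        tree = simulate_dated_tree(cfg)
        hist = simulate_biogeography(tree, areas, cfg)
        replayed = _replay(hist)
        assert replayed == hist.tip_areas


def test_dispersal_rate_calibration():
    """Realized dispersals per lineage-Ma within 3 SE of the nominal rate."""
    reps, d_rate = 200, 0.1
    rng = np.random.default_rng(5)
    per_rep = []
    for _ in range(reps):
        cfg = SimulationConfig(n_species=8, dispersal_rate=d_rate,
                               extinction_rate=0.4, area_count=6,
                               seed=int(rng.integers(2**31 - 1)))
        tree = simulate_dated_tree(cfg, np.random.default_rng(cfg.seed))
        hist = simulate_biogeography(tree, default_area_system(6), cfg)
        it = IndexedTree(tree)
        ages = it.ages_from_edges()
        total_time = sum(ages[it.parent[v]] - ages[v]
                         for v in range(it.n_nodes) if it.parent[v] >= 0)
        n_disp = sum(e.kind == "dispersal" for e in hist.events)
        per_rep.append(n_disp / total_time)
    per_rep = np.array(per_rep)
    se = per_rep.std(ddof=1) / np.sqrt(reps)
    assert abs(per_rep.mean() - d_rate) < 3 * se


# -------------------------------------------------------------------- alignment


def test_zero_rate_alignment_is_constant():
    cfg = SimulationConfig(n_species=5, clock_rate_mean=0.0, seed=4,
                           seq_length=300)
    cfg.birth_rate = 0.3
    tree = simulate_dated_tree(cfg)
    # clock_rate_mean=0 passes validation (rates >= 0)
    records, _ = simulate_alignment(tree, cfg)
    seqs = {s for _, s in records}
    assert len(seqs) == 1


def test_alignment_seed_determinism_and_shape():
    cfg = SimulationConfig(n_species=4, seed=9, seq_length=333)
    tree = simulate_dated_tree(cfg)
    r1, rates1 = simulate_alignment(tree, cfg)
    r2, rates2 = simulate_alignment(tree, cfg)
    assert r1 == r2 and rates1 == rates2
    assert all(len(s) == 333 for _, s in r1)
    assert len(r1) == 4


def test_strict_clock_pairwise_distance_matches_hky_expectation():
    t, r = 4.0, 0.01
    cfg = SimulationConfig(n_species=2, clock_rate_mean=r, seq_length=100_000,
                           seed=6)
    from vicarange.trees import read_tree

    tree = read_tree(f"(A:{t},B:{t});")
    records, _ = simulate_alignment(tree, cfg)
    a, b = records[0][1], records[1][1]
    observed = np.mean([x != y for x, y in zip(a, b)])
    expected = hky_distance_expectation(2 * r * t, cfg.kappa, cfg.base_freqs)
    se = np.sqrt(expected * (1 - expected) / cfg.seq_length)
    assert abs(observed - expected) < 3 * se


def test_root_sequence_has_no_internal_stops():
    from vicarange.seqprep import check_coding

    cfg = SimulationConfig(n_species=2, clock_rate_mean=0.0, seq_length=900,
                           seed=8)
    from vicarange.trees import read_tree

    tree = read_tree("(A:1,B:1);")
    records, _ = simulate_alignment(tree, cfg)
    assert check_coding(records) == []


def test_relaxed_clock_rates_vary():
    cfg = SimulationConfig(n_species=6, clock_model="lognormal-relaxed",
                           relaxed_sd=0.005, seed=10)
    tree = simulate_dated_tree(cfg)
    _, rates = simulate_alignment(tree, cfg)
    vals = np.array(list(rates.values()))
    assert vals.std() > 0
    assert abs(vals.mean() - cfg.clock_rate_mean) < 5 * cfg.relaxed_sd


def test_expand_haplotypes_keeps_ultrametric():
    cfg = SimulationConfig(n_species=5, haplotypes_per_species=3, seed=12)
    rng = np.random.default_rng(12)
    sp = simulate_dated_tree(cfg, rng)
    tree, tip_species = expand_haplotypes(sp, cfg, rng)
    assert len(tree.leaf_nodes()) == 15
    assert is_ultrametric(tree, tol=1e-6)
    assert set(tip_species.values()) == {l.taxon.label for l in sp.leaf_node_iter()}


def test_dataset_bundle_consistency():
    cfg = SimulationConfig(n_species=6, haplotypes_per_species=2, seed=13)
    hist, records = simulate_dataset(cfg)
    labels = {l for l, _ in records}
    assert labels == set(hist.tip_areas) == set(hist.tip_species)
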