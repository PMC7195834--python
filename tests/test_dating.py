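"""Calibration schemes, MCMC node dating, summaries, model comparison."""

import numpy as np
import pytest

from vicarange.dating import (
    Calibration,
    CalibrationScheme,
    ClockModel,
    McmcSettings,
    build_calibration_scheme,
    compare_clock_models,
    effective_sample_size,
    estimate_node_ages,
    hpd_interval,
    summarize_ages,
)
from vicarange.simulate import SimulationConfig, simulate_alignment, simulate_dated_tree
from vicarange.trees import IndexedTree, read_tree


# ------------------------------------------------------------------ schemes


def test_scheme_I_constraints():
    s = build_calibration_scheme("I")
    by_name = {c.name: c for c in s.constraints}
    assert len(s.constraints) == 3
    assert by_name["heroini_fossil"].mean == 44.25
    assert by_name["heroini_fossil"].sd == 2.7
    assert by_name["cuba_hispaniola"].mean == 22.5
    assert by_name["cuba_hispaniola"].sd == 1.5
    assert by_name["orinoco_magdalena"].mean == 10.95
    assert by_name["orinoco_magdalena"].sd == 0.6


def test_scheme_II_drops_fossil_III_keeps_only_it():
    s2 = build_calibration_scheme("II")
    assert len(s2.constraints) == 2
    assert all(c.name != "heroini_fossil" for c in s2.constraints)
    s3 = build_calibration_scheme("III")
    assert [c.name for c in s3.constraints] == ["heroini_fossil"]


def test_scheme_IV_and_V():
    s4 = build_calibration_scheme("IV")
    assert len(s4.constraints) == 1
    assert (s4.constraints[0].mean, s4.constraints[0].sd) == (23.0, 2.0)
    s5 = build_calibration_scheme("V")
    assert s5.constraints[0].mean == 7.5
    assert s5.constraints[0].sd == 0.5  # configurable default
    assert build_calibration_scheme("V", pdm_sd=1.0).constraints[0].sd == 1.0
    with pytest.raises(KeyError):
        build_calibration_scheme("VI")


def test_scheme_binding_and_validation():
    s = build_calibration_scheme("IV").with_tips(
        {"caquetaia_split": ("A", "B")}
    )
    assert s.constraints[0].tips == ("A", "B")
    with pytest.raises(KeyError):
        build_calibration_scheme("IV").with_tips({})
    with pytest.raises(ValueError):
        Calibration("x", 5.0, 0.0)


# ---------------------------------------------------------------- summaries


def test_hpd_and_median_degenerate_and_exact():
    assert hpd_interval(np.full(100, 3.0)) == (3.0, 3.0)
    draws = np.arange(1, 101, dtype=float)
    assert float(np.median(draws)) == 50.5


def test_hpd_matches_normal_quantiles():
    rng = np.random.default_rng(0)
    draws = rng.normal(10.0, 1.0, 20_000)
    lo, hi = hpd_interval(draws, 0.95)
    assert lo == pytest.approx(10 - 1.96, abs=0.08)
    assert hi == pytest.approx(10 + 1.96, abs=0.08)


def test_summarize_requires_draws():
    tree = read_tree("((A:1,B:1):1,C:2);")
    scheme = CalibrationScheme(
        "s", (Calibration("root", 2.0, 0.5, ("A", "B", "C")),)
    )
    sample = estimate_node_ages(
        [("A", "ACGT"), ("B", "ACGT"), ("C", "ACGT")], tree, scheme,
        settings=McmcSettings(n_sweeps=50), seed=1,
    )
    df = summarize_ages(sample)
    assert {"median", "hpd_lower", "hpd_upper", "ess"} <= set(df.columns)
    sample.ages = sample.ages[:0]
    with pytest.raises(ValueError):
        summarize_ages(sample)


def test_ess_white_noise_close_to_n():
    x = np.random.default_rng(1).normal(size=2000)
    assert effective_sample_size(x) > 1000


# ------------------------------------------------------------------ sampler


def test_prior_only_recovers_calibration_priors():
    """With the likelihood off and a flat ordering prior, calibrated node
    marginals match their truncated-normal priors within Monte-Carlo error."""
    tree = read_tree("((A:5,B:5):15,C:20);")
    scheme = CalibrationScheme("prior", (
        Calibration("root", 20.0, 1.0, ("A", "B", "C")),
        Calibration("cherry", 5.0, 0.5, ("A", "B")),
    ))
    recs = [("A", "ACGT"), ("B", "ACGT"), ("C", "ACGT")]
    sample = estimate_node_ages(
        recs, tree, scheme,
        settings=McmcSettings(n_sweeps=20000, tree_prior="uniform"),
        seed=7, use_likelihood=False,
    )
    it = sample.itree
    for tips, mean, sd in ((("A", "B", "C"), 20.0, 1.0), (("A", "B"), 5.0, 0.5)):
        draws = sample.ages[:, it.mrca(tips)]
        ess = effective_sample_size(draws)
        se_mean = sd / np.sqrt(ess)
        assert abs(draws.mean() - mean) < 3 * se_mean
        se_sd = sd / np.sqrt(2 * ess)
        assert abs(draws.std() - sd) < 3 * se_sd


def test_two_taxon_limits():
    """Tight calibration pins the root at the prior mean; a diffuse prior
    lets the data place it near d/(2r)."""
    t_true, r = 5.0, 0.01
    cfg = SimulationConfig(n_species=2, clock_rate_mean=r, seq_length=20_000,
                           seed=77)
    tree = read_tree(f"(A:{t_true},B:{t_true});")
    records, _ = simulate_alignment(tree, cfg)
    clock = ClockModel(rate_prior_median=r, rate_prior_sigma=0.02)  # ~fixed rate
    settings = McmcSettings(n_sweeps=2000, gamma_ncat=1)

    tight = CalibrationScheme("t", (Calibration("root", 8.0, 0.05, ("A", "B")),))
    s1 = estimate_node_ages(records, tree, tight, clock=clock,
                            settings=settings, seed=5)
    root = s1.itree.mrca(["A", "B"])
    assert np.median(s1.ages[:, root]) == pytest.approx(8.0, abs=0.2)

    diffuse = CalibrationScheme("d", (Calibration("root", 10.0, 8.0, ("A", "B")),))
    s2 = estimate_node_ages(records, tree, diffuse, clock=clock,
                            settings=settings, seed=5)
    assert np.median(s2.ages[:, root]) == pytest.approx(t_true, rel=0.15)


def test_requires_calibration_and_bound_tips():
    tree = read_tree("((A:1,B:1):1,C:2);")
    recs = [("A", "ACGT"), ("B", "ACGT"), ("C", "ACGT")]
    with pytest.raises(ValueError):
        estimate_node_ages(recs, tree, CalibrationScheme("none", ()), seed=1)
    with pytest.raises(ValueError):
        estimate_node_ages(
            recs, tree,
            CalibrationScheme("u", (Calibration("x", 5.0, 1.0),)), seed=1,
        )


def test_posterior_respects_node_ordering():
    cfg = SimulationConfig(n_species=6, seed=15)
    rng = np.random.default_rng(15)
    tree = simulate_dated_tree(cfg, rng)
    records, _ = simulate_alignment(tree, cfg, rng)
    it = IndexedTree(tree)
    ages = it.ages_from_edges()
    scheme = CalibrationScheme(
        "r", (Calibration("root", float(ages[it.root]), 0.5,
                          tuple(it.tip_labels)),)
    )
    sample = estimate_node_ages(records, tree, scheme,
                                settings=McmcSettings(n_sweeps=400), seed=2)
    for v in it.postorder_internal:
        l, r = it.children[v - it.n_tips]
        assert (sample.ages[:, v] > sample.ages[:, l] - 1e-12).all()
        assert (sample.ages[:, v] > sample.ages[:, r] - 1e-12).all()
        assert (sample.ages[:, v] > 0).all()


def test_identical_sequences_tip_permutation_invariance():
    """Swapping the labels of identical sequences leaves the strict-clock
    posterior unchanged (same seed)."""
    tree1 = read_tree("((A:1,B:1):1,C:2);")
    tree2 = read_tree("((B:1,A:1):1,C:2);")
    recs = [("A", "ACGTACGT"), ("B", "ACGTACGT"), ("C", "ACGAACGA")]
    scheme = CalibrationScheme("s", (Calibration("root", 2.0, 0.3,
                                                 ("A", "B", "C")),))
    s1 = estimate_node_ages(recs, tree1, scheme,
                            settings=McmcSettings(n_sweeps=600), seed=3)
    s2 = estimate_node_ages(recs, tree2, scheme,
                            settings=McmcSettings(n_sweeps=600), seed=3)
    assert np.allclose(s1.ages, s2.ages)


def test_miscalibration_compresses_the_whole_tree():
    """Calibrating a node at half its true age scales every other node down
    by roughly the same factor (the barrier-test failure mode)."""
    cfg = SimulationConfig(n_species=8, seed=41)
    rng = np.random.default_rng(41)
    tree = simulate_dated_tree(cfg, rng)
    records, _ = simulate_alignment(tree, cfg, rng)
    it = IndexedTree(tree)
    true_ages = it.ages_from_edges()
    half = CalibrationScheme(
        "V-like",
        (Calibration("root", float(true_ages[it.root]) / 2, 0.3,
                     tuple(it.tip_labels)),),
    )
    sample = estimate_node_ages(records, tree, half,
                                settings=McmcSettings(n_sweeps=1500), seed=4)
    ratios = [
        np.median(sample.ages[:, v]) / true_ages[v]
        for v in it.postorder_internal
        if true_ages[v] > 0.5  # skip very young nodes (noisy ratios)
    ]
    assert np.median(ratios) == pytest.approx(0.5, abs=0.12)


# ---------------------------------------------------------- model comparison


def _tiny_dataset(seed):
    cfg = SimulationConfig(n_species=5, seed=seed, seq_length=600)
    rng = np.random.default_rng(seed)
    tree = simulate_dated_tree(cfg, rng)
    records, _ = simulate_alignment(tree, cfg, rng)
    it = IndexedTree(tree)
    ages = it.ages_from_edges()
    scheme = CalibrationScheme(
        "s", (Calibration("root", float(ages[it.root]), 0.5,
                          tuple(it.tip_labels)),)
    )
    return records, tree, scheme


def test_self_comparison_within_mc_error():
    records, tree, scheme = _tiny_dataset(11)
    df = compare_clock_models(
        records, tree, scheme,
        [ClockModel("strict"), ClockModel("strict")],
        settings=McmcSettings(n_sweeps=500, gamma_ncat=1), seed=3, n_rungs=8,
    )
    diff = abs(df.log_marginal_likelihood.iloc[0] - df.log_marginal_likelihood.iloc[1])
    se = np.hypot(df.mc_se.iloc[0], df.mc_se.iloc[1])
    assert diff < 2.5 * se + 0.5


def test_strict_clock_selected_on_strict_data():
    wins = 0
    for i in range(3):
        records, tree, scheme = _tiny_dataset(100 + i)
        df = compare_clock_models(
            records, tree, scheme,
            [ClockModel("strict"), ClockModel("ucln")],
            settings=McmcSettings(n_sweeps=800, gamma_ncat=1),
            seed=3 + i, n_rungs=12,
        )
        wins += df.iloc[0]["model"] == "strict"
    assert wins >= 2


def test_needs_two_candidates():
    records, tree, scheme = _tiny_dataset(11)
    with pytest.raises(ValueError):
        compare_clock_models(records, tree, scheme, [ClockModel("strict")])
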