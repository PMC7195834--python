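"""Reusable validation experiments run under the package's study conditions.

Each function simulates data with known truth using the generators in
:mod:`vicarange.simulate`, runs the corresponding estimator, and returns a
scalar score (a coverage, a recovery rate, an agreement fraction).  They are
shared between the test suite and the reproduction script so both measure
the same thing the same way.
"""

from __future__ import annotations

import numpy as np

from .dating import (
    Calibration,
    CalibrationScheme,
    ClockModel,
    McmcSettings,
    build_calibration_scheme,
    estimate_node_ages,
    hpd_interval,
    summarize_ages,
)
from .delimit import gmyc_single_threshold, ptp_delimit
from .diva import AreaSystem, diva_exhaustive, diva_optimize
from .extinction import DISPERSAL_EXT, classify_tree
from .likelihood import HKYModel, PruningLikelihood, loglik_bruteforce
from .pipeline import run_pdm_test
from .simulate import (
    SimulationConfig,
    default_area_system,
    simulate_alignment,
    simulate_biogeography,
    simulate_dated_tree,
)
from .trees import IndexedTree, read_tree

__all__ = [
    "random_coalescent_newick",
    "diva_oracle_agreement",
    "pruning_oracle_max_error",
    "age_coverage_experiment",
    "gmyc_recovery_rate",
    "ptp_recovery_rate",
    "zero_extinction_fp_rate",
    "pdm_verdict_experiment",
]


def random_coalescent_newick(labels, rng, depth: float = 1.0) -> str:
    """Random ultrametric topology over labels (uniform joins)."""
    ages = np.sort(rng.uniform(0, depth, size=len(labels) - 1))
    ages[-1] = depth
    items = [(str(l), 0.0) for l in labels]
    for age in ages:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (sa, ta), (sb, tb) = items[i], items[j]
        merged = (f"({sa}:{age - ta:.10g},{sb}:{age - tb:.10g})", age)
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append(merged)
    return items[0][0] + ";"


# ---------------------------------------------------------------------------
# DIVA vs exhaustive enumeration


def diva_oracle_agreement(n_instances: int = 1000, seed: int = 0) -> dict:
    """Fraction of random 4-tip / 3-area instances where the dynamic program
    and exhaustive enumeration return identical costs and optimal sets."""
    rng = np.random.default_rng(seed)
    areas = AreaSystem(["a", "b", "c"], [("a", "b"), ("b", "c")])
    subsets = [
        frozenset(s)
        for s in (["a"], ["b"], ["c"], ["a", "b"], ["a", "c"], ["b", "c"],
                  ["a", "b", "c"])
    ]
    agree = 0
    for i in range(n_instances):
        tree = read_tree(random_coalescent_newick(list("WXYZ"), rng))
        maxareas = int(rng.integers(1, 4))
        valid = [s for s in subsets if len(s) <= maxareas]
        tip_areas = {t: valid[rng.integers(len(valid))] for t in "WXYZ"}
        dp = diva_optimize(tree, tip_areas, maxareas, areas)
        ex = diva_exhaustive(tree, tip_areas, maxareas, areas)
        ok = abs(dp.total_cost - ex.total_cost) < 1e-9
        if ok:
            for clade, nr in dp.nodes.items():
                if sorted(map(sorted, nr.optimal_sets)) != sorted(
                    map(sorted, ex.nodes[clade].optimal_sets)
                ):
                    ok = False
                    break
        agree += ok
    return {"agreement": agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# pruning likelihood vs brute force


def pruning_oracle_max_error(n_instances: int = 20, seed: int = 0,
                             n_sites: int = 50) -> dict:
    """Max |pruning - brute force| log-likelihood over random 4-tip datasets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        tree = read_tree(random_coalescent_newick(list("ABCD"), rng, depth=1.0))
        itree = IndexedTree(tree)
        model = HKYModel(rng.uniform(1.5, 6.0), _random_freqs(rng))
        bl = np.full(itree.n_nodes, np.nan)
        for v in range(itree.n_nodes):
            if itree.parent[v] >= 0:
                bl[v] = rng.uniform(0.01, 0.5)
        records = [
            (lbl, "".join(rng.choice(list("ACGT"), size=n_sites)))
            for lbl in itree.tip_labels
        ]
        alpha = float(rng.uniform(0.3, 2.0))
        for ga, ncat in ((None, 1), (alpha, 4)):
            fast = PruningLikelihood(itree, records).loglik(
                bl, model, gamma_alpha=ga, ncat=ncat
            )
            slow = loglik_bruteforce(itree, records, bl, model,
                                     gamma_alpha=ga, ncat=ncat)
            worst = max(worst, abs(fast - slow))
    return {"max_abs_error": worst, "n": n_instances}


def _random_freqs(rng) -> np.ndarray:
    f = rng.dirichlet([10, 10, 10, 10])
    return f / f.sum()


# ---------------------------------------------------------------------------
# strict-clock node-age recovery


def age_coverage_experiment(
    n_reps: int = 20,
    seed: int = 0,
    n_sweeps: int = 2500,
) -> dict:
    """95% HPD coverage of true node ages on strict-clock synthetic data.

    Each replicate simulates a 10-tip pure-birth tree and a 1,137 bp strict
    clock alignment, calibrates the root at its true age (SD 0.5 Ma), runs
    the MCMC, and scores which true internal ages fall inside their 95%
    HPDs.
    """
    rng = np.random.default_rng(seed)
    inside = total = 0
    settings = McmcSettings(n_sweeps=n_sweeps, gamma_ncat=1)
    for rep in range(n_reps):
        sub = int(rng.integers(2**31 - 1))
        config = SimulationConfig(
            n_species=10, birth_rate=0.3, death_rate=0.0, clock_model="strict",
            seed=sub,
        )
        rep_rng = np.random.default_rng(sub)
        tree = simulate_dated_tree(config, rep_rng)
        records, _ = simulate_alignment(tree, config, rep_rng)
        itree = IndexedTree(tree)
        true_ages = itree.ages_from_edges()
        scheme = CalibrationScheme(
            "synthetic-root",
            (Calibration("root", float(true_ages[itree.root]), 0.5,
                         tuple(itree.tip_labels)),),
        )
        sample = estimate_node_ages(
            records, tree, scheme, clock=ClockModel(kind="strict"),
            settings=settings, seed=sub,
        )
        for v in itree.postorder_internal:
            lo, hi = hpd_interval(sample.ages[:, v], 0.95)
            inside += lo <= true_ages[v] <= hi
            total += 1
    return {"coverage": inside / total, "n_nodes": total, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# species delimitation recovery


def _species_haplotype_tree(rng, n_species=5, n_haps=4, min_split=1.0,
                            within_depth=0.12):
    """Ultrametric tree with deep species splits and shallow intraspecific
    divergence (the regime both delimiters assume)."""
    from .simulate import SimulationConfig, expand_haplotypes

    config = SimulationConfig(
        n_species=n_species, haplotypes_per_species=n_haps, birth_rate=0.3,
        death_rate=0.0, within_species_depth=within_depth,
        seed=int(rng.integers(2**31 - 1)),
    )
    for _ in range(400):
        sp_tree = simulate_dated_tree(config, rng)
        ages = IndexedTree(sp_tree).ages_from_edges()
        internal_ages = ages[n_species:]
        if internal_ages.min() >= min_split:
            break
    else:
        raise RuntimeError("could not draw a deep-split species tree")
    tree, tip_species = expand_haplotypes(sp_tree, config, rng)
    return tree, tip_species


def gmyc_recovery_rate(n_reps: int = 20, seed: int = 0, n_species: int = 5) -> dict:
    """Fraction of replicates where GMYC recovers the true species count."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        tree, _ = _species_haplotype_tree(rng, n_species=n_species)
        fit, _part = gmyc_single_threshold(tree)
        hits += fit.n_entities == n_species
    return {"recovery_rate": hits / n_reps, "n_reps": n_reps}


def ptp_recovery_rate(n_reps: int = 20, seed: int = 0, n_species: int = 5,
                      clock_rate: float = 0.01, rate_jitter_sd: float = 0.3) -> dict:
    """PTP recovery on deep/shallow trees rescaled to substitutions.

    Branch lengths are branch durations times a clock rate with lognormal
    per-branch jitter, so between-species edges form a long length class and
    within-species edges a class roughly an order of magnitude shorter -
    the two-rate situation the delimiter models.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        tree, tip_species = _species_haplotype_tree(rng, n_species=n_species)
        itree = IndexedTree(tree)
        newick = _substitution_newick(itree, rng, clock_rate, rate_jitter_sd)
        part = ptp_delimit(read_tree(newick), n_restarts=30,
                           seed=int(rng.integers(2**31 - 1)))
        hits += part.n_clusters == n_species
    return {"recovery_rate": hits / n_reps, "n_reps": n_reps}


def _substitution_newick(itree, rng, rate, jitter_sd):
    def render(v):
        if v < itree.n_tips:
            return itree.tip_labels[v]
        l, r = itree.children[v - itree.n_tips]
        parts = []
        for c in (l, r):
            bl = itree.edge_length[c] * rate * rng.lognormal(0.0, jitter_sd)
            parts.append(f"{render(c)}:{bl:.8g}")
        return f"({parts[0]},{parts[1]})"

    return render(itree.root) + ";"


# ---------------------------------------------------------------------------
# extinction-rule false positives


def zero_extinction_fp_rate(n_reps: int = 100, seed: int = 0) -> dict:
    """Fraction of nodes called dispersal_with_extinction on histories
    simulated with zero extinction and adjacency-respecting dispersal."""
    rng = np.random.default_rng(seed)
    fp = total = 0
    for _ in range(n_reps):
        config = SimulationConfig(
            n_species=8, birth_rate=0.3, death_rate=0.0, area_count=6,
            dispersal_rate=0.1, extinction_rate=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        areas = default_area_system(config.area_count)
        rep_rng = np.random.default_rng(config.seed)
        tree = simulate_dated_tree(config, rep_rng)
        history = simulate_biogeography(tree, areas, config, rep_rng)
        recon = diva_optimize(tree, history.tip_areas, len(areas.labels), areas)
        for cls in classify_tree(recon, tree, areas, history.tip_areas):
            fp += cls.verdict == DISPERSAL_EXT
            total += 1
    return {"fp_rate": fp / total, "n_nodes": total, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# end-to-end barrier test


def _barrier_dataset(rng, focal_age: float, ingroup_crown: float,
                     root_age: float = 20.0, n_ingroup: int = 8):
    labels = [f"I{i+1}" for i in range(n_ingroup)]
    ingroup = random_coalescent_newick(labels, rng, depth=ingroup_crown)[:-1]
    newick = (
        f"(({ingroup}:{focal_age - ingroup_crown:.10g},SIS:{focal_age:.10g})"
        f":{root_age - focal_age:.10g},OUT:{root_age:.10g});"
    )
    tree = read_tree(newick)
    config = SimulationConfig(seed=int(rng.integers(2**31 - 1)))
    records, _ = simulate_alignment(tree, config, np.random.default_rng(config.seed))
    return tree, records, tuple(labels) + ("SIS",)


def pdm_verdict_experiment(
    n_reps: int = 20,
    seed: int = 0,
    focal_age: float = 14.0,
    barrier_window: tuple[float, float] = (5.0, 7.5),
    n_sweeps: int = 2000,
    include_barrier_scheme: bool = True,
) -> dict:
    """Fraction of replicates with a 'predates barrier' verdict.

    Truth places the focal split at ``focal_age`` (14 Ma by default, against
    a 5-7.5 Ma barrier window).  The barrier-free scheme calibrates the root
    at its true 20 Ma age; the barrier scheme (contrast only) calibrates the
    focal split at 7.5 Ma.
    """
    rng = np.random.default_rng(seed)
    verdicts = []
    settings = McmcSettings(n_sweeps=n_sweeps, gamma_ncat=1)
    for rep in range(n_reps):
        tree, records, focal_tips = _barrier_dataset(
            rng, focal_age=focal_age, ingroup_crown=min(10.0, 0.7 * focal_age)
        )
        all_tips = tuple(sorted(l for l in focal_tips) + ["OUT"])
        free = CalibrationScheme(
            "II", (Calibration("root_geo", 20.0, 1.0, all_tips),)
        )
        schemes = [free]
        if include_barrier_scheme:
            schemes.append(
                build_calibration_scheme("V").with_tips({"pdm_barrier": focal_tips})
            )
        report = run_pdm_test(
            records, tree, schemes, focal_tips,
            barrier_window=barrier_window, settings=settings,
            seed=int(rng.integers(2**31 - 1)),
        )
        verdicts.append(report["verdict"])
    frac = sum(v == "predates barrier" for v in verdicts) / len(verdicts)
    return {"predates_fraction": frac, "n_reps": n_reps, "verdicts": verdicts}
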