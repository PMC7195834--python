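"""Single-locus species delimitation: single-threshold GMYC and a PTP-style
two-rate branch-length model, plus a cross-method concordance summary.

GMYC models an ultrametric tree as a Yule process between species switching
to neutral coalescents within species at a threshold time; the threshold is
profiled over node heights by maximum likelihood and tested against the
single-process null with a likelihood-ratio test.  The PTP variant works on
substitution-scaled trees, assigning edges to between- vs within-species
exponential classes consistent with a partition into connected subtrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .trees import IndexedTree, is_ultrametric

__all__ = [
    "DelimitationPartition",
    "GmycFit",
    "gmyc_single_threshold",
    "ptp_delimit",
    "ptp_exhaustive",
    "concordance",
    "gmyc_interval_loglik",
]


@dataclass
class DelimitationPartition:
    """tip -> cluster id (contiguous ids), tagged by method."""

    assignments: dict[str, int]
    method: str
    support: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        ids = sorted(set(self.assignments.values()))
        if ids != list(range(len(ids))):
            remap = {c: i for i, c in enumerate(ids)}
            self.assignments = {t: remap[c] for t, c in self.assignments.items()}
            self.support = {remap[c]: s for c, s in self.support.items() if c in remap}

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def clusters(self) -> list[frozenset[str]]:
        out: dict[int, set[str]] = {}
        for t, c in self.assignments.items():
            out.setdefault(c, set()).add(t)
        return [frozenset(out[c]) for c in sorted(out)]


@dataclass
class GmycFit:
    threshold_age: float
    lambda_yule: float
    lambda_coal: float
    p_yule: float
    p_coal: float
    loglik_threshold: float
    loglik_null: float
    lr: float
    p_value: float
    n_entities: int


# ---------------------------------------------------------------------------
# GMYC


def _gmyc_interval_data(itree: IndexedTree, ages: np.ndarray, k: int):
    """Per-interval (x_i, yule_count, coal_term) for k diversification nodes.

    Internal nodes sorted oldest first (parents before children on age
    ties); the first k are the between-species (Yule) part.  Interval i runs
    from the i-th to the (i+1)-th node age; during it there are i+1
    lineages.
    """
    order = _age_order(itree, ages)
    n = itree.n_tips
    times = [ages[v] for v in order]
    div_set = set(order[:k])
    # cluster id per node/tip: cluster roots are the lineages hanging just
    # below the diversification part
    cluster_of = {}

    def assign(v, cl):
        cluster_of[v] = cl
        if v >= itree.n_tips:
            for c in itree.children[v - itree.n_tips]:
                assign(c, cl)

    roots = []
    for v in order[:k]:
        for c in itree.children[v - itree.n_tips]:
            if c not in div_set:
                roots.append(c)
    if k == 0:
        roots = [itree.root]
    for cl, v in enumerate(roots):
        assign(v, cl)

    xs, yule_counts, coal_terms, is_event = [], [], [], []
    n_clusters = len(roots)
    # active within-cluster lineage counts as we sweep from old to young
    counts = {cl: 1 for cl in range(n_clusters)}
    times = times + [0.0]  # final, event-free interval down to the tips
    for i in range(len(order)):
        x = times[i] - times[i + 1]
        v = order[i]
        if v not in div_set:
            counts[cluster_of[v]] += 1
        if i + 1 <= k - 1:
            yule = i + 2  # lineages during interval, all between-species
            coal = 0.0
        else:
            yule = n_clusters
            coal = float(sum(c * (c - 1) for c in counts.values()))
        xs.append(x)
        yule_counts.append(yule)
        coal_terms.append(coal)
        is_event.append(i + 1 < len(order))
    return (
        np.array(xs),
        np.array(yule_counts, float),
        np.array(coal_terms),
        np.array(is_event, dtype=bool),
    )


def _age_order(itree: IndexedTree, ages: np.ndarray) -> list[int]:
    # oldest first; age ties broken by depth (parents before children) and
    # then by clade content, so the order is invariant to tip relabeling
    depth = np.zeros(itree.n_nodes, dtype=int)
    for v in itree.postorder_internal[::-1]:
        for c in itree.children[v - itree.n_tips]:
            depth[c] = depth[v] + 1
    return sorted(
        itree.postorder_internal,
        key=lambda v: (-ages[v], depth[v], sorted(itree.clade_labels(v))),
    )


def gmyc_interval_loglik(
    xs: np.ndarray,
    yule_counts: np.ndarray,
    coal_terms: np.ndarray,
    lam_y: float,
    lam_c: float,
    p_y: float = 1.0,
    p_c: float = 1.0,
    is_event: np.ndarray | None = None,
) -> float:
    """Sum over inter-event intervals of log(b_i) - b_i * x_i, with
    b_i = lam_y * k_i^p_y + lam_c * sum_j (n_j (n_j - 1))^p_c.

    The final interval down to the tips terminates in no event
    (``is_event`` False there) and contributes only the survival term
    exp(-b_i x_i).
    """
    if is_event is None:
        is_event = np.ones_like(xs, dtype=bool)
    b = lam_y * yule_counts**p_y + lam_c * np.where(
        coal_terms > 0, coal_terms, 0.0
    ) ** p_c * (coal_terms > 0)
    if (b <= 0).any():
        return -np.inf
    return float(np.sum(np.log(b) * is_event - b * xs))


def _fit_rates(xs, yule_counts, coal_terms, is_event, p_y, p_c):
    has_coal = (coal_terms > 0).any()

    def nll(logparams):
        lam_y = math.exp(logparams[0])
        lam_c = math.exp(logparams[1]) if has_coal else 0.0
        return -gmyc_interval_loglik(xs, yule_counts, coal_terms, lam_y, lam_c,
                                     p_y, p_c, is_event)

    x0 = np.array([math.log(max(1.0 / max(xs.mean(), 1e-9), 1e-6))] * 2)
    res = minimize(nll, x0 if has_coal else x0[:1].repeat(2), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    lam_y = math.exp(res.x[0])
    lam_c = math.exp(res.x[1]) if has_coal else 0.0
    return lam_y, lam_c, -res.fun


def gmyc_single_threshold(
    tree: dendropy.Tree,
    p_yule: float = 1.0,
    p_coal: float = 1.0,
    lr_df: int = 2,
    alpha: float | None = 0.05,
) -> tuple[GmycFit, DelimitationPartition]:
    """Single-threshold GMYC fit on an ultrametric tree.

    Profiles the threshold over candidate node heights, fitting the Yule and
    coalescent rates by ML for each; the null model is a single branching
    process over the whole tree.  The LR test uses a one-tailed chi-square
    with ``lr_df`` degrees of freedom (2 by default: one extra rate plus the
    threshold).  Scaling exponents are fixed (1 by default).  When the
    threshold model is not significant at ``alpha``, the reported partition
    is the null's: every branching is diversification and every tip its own
    entity (``alpha=None`` reports the raw ML partition regardless).
    """
    itree = IndexedTree(tree)
    if itree.n_tips < 3:
        raise ValueError("GMYC needs at least 3 tips")
    if not is_ultrametric(tree, tol=1e-4 * _tree_depth(tree)):
        raise ValueError("GMYC requires an ultrametric tree")
    ages = itree.ages_from_edges()
    n = itree.n_tips
    order = _age_order(itree, ages)

    best = None
    ll_null = None
    for k in range(1, n):  # number of between-species nodes
        xs, yc, ct, ev = _gmyc_interval_data(itree, ages, k)
        lam_y, lam_c, ll = _fit_rates(xs, yc, ct, ev, p_yule, p_coal)
        if best is None or ll > best[0] + 1e-12:
            best = (ll, k, lam_y, lam_c)
        if k == n - 1:
            # all nodes diversification: the single-process null
            ll_null = ll
    ll_best, k_best, lam_y, lam_c = best

    lr = max(0.0, 2.0 * (ll_best - ll_null))
    p_value = float(chi2.sf(lr, lr_df))
    if alpha is not None and p_value >= alpha:
        # no significant within-species clustering: report the null, under
        # which every branching is a speciation and every tip is an entity
        k_best = n - 1
    threshold_age = float(ages[order[k_best]]) if k_best < n - 1 else 0.0

    div_set = set(order[:k_best])
    roots = []
    for v in order[:k_best]:
        for c in itree.children[v - itree.n_tips]:
            if c not in div_set:
                roots.append(c)
    assignments: dict[str, int] = {}
    for cl, v in enumerate(sorted(roots)):
        for t in itree.clades[v] if v >= itree.n_tips else [v]:
            assignments[itree.tip_labels[t]] = cl
    partition = DelimitationPartition(assignments, method="gmyc")
    fit = GmycFit(
        threshold_age=threshold_age,
        lambda_yule=lam_y,
        lambda_coal=lam_c,
        p_yule=p_yule,
        p_coal=p_coal,
        loglik_threshold=ll_best,
        loglik_null=ll_null,
        lr=lr,
        p_value=p_value,
        n_entities=partition.n_clusters,
    )
    return fit, partition


def _tree_depth(tree: dendropy.Tree) -> float:
    from .trees import node_ages

    return max(node_ages(tree).values()) or 1.0


# ---------------------------------------------------------------------------
# PTP


def _crown_partition_loglik(itree: IndexedTree, lengths: np.ndarray,
                            crowns: frozenset[int]) -> float:
    """Two-class exponential likelihood of a crown set.

    Edges strictly inside crown subtrees are 'within'; all others
    'between'.  Rates are profiled out analytically.  Two constraints keep
    the model identifiable: the single-class partition (one species spanning
    the root, no between edges) is excluded, and when both classes are
    populated the within-species mean must be strictly shorter than the
    between-species mean (coalescent branches are shorter than speciation
    branches); violating partitions score -inf.
    """
    within = []
    between = []
    inside = np.zeros(itree.n_nodes, dtype=bool)
    for v in sorted(crowns, reverse=True):
        if v >= itree.n_tips:
            stack = list(itree.children[v - itree.n_tips])
            while stack:
                c = stack.pop()
                inside[c] = True
                if c >= itree.n_tips:
                    stack.extend(itree.children[c - itree.n_tips])
    for v in range(itree.n_nodes):
        if itree.parent[v] < 0:
            continue
        (within if inside[v] else between).append(lengths[v])
    if not between:
        return -math.inf
    if within and sum(within) / len(within) >= sum(between) / len(between):
        return -math.inf
    ll = 0.0
    for grp in (within, between):
        n = len(grp)
        if n == 0:
            continue
        s = max(sum(grp), 1e-12 * n)
        ll += n * math.log(n / s) - n
    return ll


def _valid_crown_sets(itree: IndexedTree):
    """All crown sets (each tip covered by exactly one crown)."""

    def options(v) -> list[frozenset[int]]:
        out = [frozenset([v])]
        if v >= itree.n_tips:
            l, r = itree.children[v - itree.n_tips]
            for a in options(l):
                for b in options(r):
                    out.append(a | b)
        return out

    return options(itree.root)


def ptp_exhaustive(tree: dendropy.Tree) -> DelimitationPartition:
    """Reference PTP: exhaustive search over all valid partitions (small trees)."""
    itree = IndexedTree(tree)
    lengths = itree.edge_length.copy()
    _check_lengths(lengths, itree)
    best = None
    for crowns in _valid_crown_sets(itree):
        ll = _crown_partition_loglik(itree, lengths, crowns)
        key = (ll, -len(crowns))
        if best is None or key > best[0]:
            best = (key, crowns)
    return _crowns_to_partition(itree, best[1], method="ptp-exhaustive")


def _check_lengths(lengths, itree):
    vals = [lengths[v] for v in range(itree.n_nodes) if itree.parent[v] >= 0]
    if any(v is None or np.isnan(v) for v in vals):
        raise ValueError("tree must have branch lengths on every edge")
    if all(v <= 0 for v in vals):
        raise ValueError("all branch lengths are zero")


def _crowns_to_partition(itree, crowns, method):
    assignments = {}
    for cl, v in enumerate(sorted(crowns)):
        tips = itree.clades[v] if v >= itree.n_tips else frozenset([v])
        for t in tips:
            assignments[itree.tip_labels[t]] = cl
    return DelimitationPartition(assignments, method=method)


def ptp_delimit(
    tree: dendropy.Tree,
    n_restarts: int = 50,
    seed: int = 0,
) -> DelimitationPartition:
    """PTP-style delimitation on a substitution-scaled tree.

    Greedy hill-climbing over crown sets (split a species into its two
    child clades / merge two sibling species) from ``n_restarts`` random
    starts; ties are broken toward fewer species.
    """
    itree = IndexedTree(tree)
    if itree.n_tips < 3:
        raise ValueError("PTP needs at least 3 tips")
    lengths = itree.edge_length.copy()
    _check_lengths(lengths, itree)
    rng = np.random.default_rng(seed)

    def random_crowns(q: float) -> frozenset[int]:
        crowns = set()
        stack = [itree.root]
        while stack:
            v = stack.pop()
            if v < itree.n_tips or rng.random() < q:
                crowns.add(v)
            else:
                stack.extend(itree.children[v - itree.n_tips])
        return frozenset(crowns)

    def neighbors(crowns: frozenset[int]):
        for v in crowns:
            if v >= itree.n_tips:
                l, r = itree.children[v - itree.n_tips]
                yield (crowns - {v}) | {l, r}
        by_parent: dict[int, list[int]] = {}
        for v in crowns:
            p = itree.parent[v]
            if p >= 0:
                by_parent.setdefault(p, []).append(v)
        for p, kids in by_parent.items():
            if len(kids) == 2:
                yield (crowns - set(kids)) | {p}

    best_global = None
    for restart in range(n_restarts):
        if restart == 0:
            crowns = frozenset(range(itree.n_tips))  # all singletons
        else:
            crowns = random_crowns(rng.uniform(0.1, 0.9))
        ll = _crown_partition_loglik(itree, lengths, crowns)
        improved = True
        while improved:
            improved = False
            for cand in neighbors(crowns):
                cll = _crown_partition_loglik(itree, lengths, cand)
                if cll > ll + 1e-12 or (
                    abs(cll - ll) <= 1e-12 and len(cand) < len(crowns)
                ):
                    crowns, ll = cand, cll
                    improved = True
                    break
        if best_global is None:
            best_global = (ll, crowns)
        else:
            bll, bcrowns = best_global
            if ll > bll + 1e-12 or (abs(ll - bll) <= 1e-12 and len(crowns) < len(bcrowns)):
                best_global = (ll, crowns)
    return _crowns_to_partition(itree, best_global[1], method="ptp")


# ---------------------------------------------------------------------------
# concordance


def concordance(
    partitions: list[DelimitationPartition],
    reference: dict[str, str],
) -> dict:
    """Per-reference-species agreement across delimitation methods.

    For each reference species and method the status is ``exact`` (one
    cluster equals the species), ``split`` (the species is a union of
    several clusters), ``merged`` (a cluster strictly contains it) or
    ``mixed``.  The consensus count is the number of species recovered
    exactly by every method.
    """
    tipsets = {frozenset(p.assignments) for p in partitions}
    if len(tipsets) != 1:
        raise ValueError("partitions cover different tip sets")
    if tipsets and frozenset(reference) != next(iter(tipsets)):
        raise ValueError("reference table does not match partition tips")
    species: dict[str, set[str]] = {}
    for tip, sp in reference.items():
        species.setdefault(sp, set()).add(tip)
    report: dict[str, dict[str, str]] = {}
    for sp, tips in species.items():
        report[sp] = {}
        for part in partitions:
            clusters = [c for c in part.clusters() if c & tips]
            if len(clusters) == 1 and clusters[0] == tips:
                status = "exact"
            elif all(c <= tips for c in clusters):
                status = "split"
            elif len(clusters) == 1 and clusters[0] > tips:
                status = "merged"
            else:
                status = "mixed"
            report[sp][part.method] = status
    consensus = sum(
        1
        for sp in species
        if all(st == "exact" for st in report[sp].values())
    )
    return {
        "per_species": report,
        "consensus_count": consensus,
        "n_species": len(species),
        "methods": [p.method for p in partitions],
    }
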