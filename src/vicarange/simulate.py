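"""Synthetic data generator with known ground truth.

Emulates a single-locus (cytochrome-b-like) phylogeographic dataset: a dated
birth-death species tree on a 0-30 Ma scale, a biogeographic history of
dispersal, vicariance, duplication and extinction over a graph of adjacent
endemic areas, and a clock-evolved protein-coding alignment (~1.1 kb) under
HKY with either a strict or an uncorrelated-lognormal relaxed clock.  Every
stage records its truth so downstream estimators can be scored against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .diva import AreaSystem
from .likelihood import VERTEBRATE_MITO_STOPS, HKYModel
from .trees import IndexedTree, read_tree

__all__ = [
    "SimulationConfig",
    "TrueHistory",
    "BioEvent",
    "simulate_dated_tree",
    "simulate_biogeography",
    "simulate_alignment",
    "expand_haplotypes",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults mirror the kind of dataset the pipeline is designed for: ~10
    species of a dispersal-limited freshwater clade, a 1,137 bp mitochondrial
    coding marker, 6 endemic areas on an adjacency graph, and tree depths
    within 0-30 Ma.
    """

    n_species: int = 10
    haplotypes_per_species: int = 1
    birth_rate: float = 0.3  # speciations / lineage / Ma
    death_rate: float = 0.0
    root_age_bound: float = 30.0  # Ma; condition by rejection
    clock_rate_mean: float = 0.01  # substitutions / site / Ma
    clock_model: str = "strict"  # or "lognormal-relaxed"
    relaxed_sd: float = 0.005  # SD of the branch-rate distribution (real space)
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.3, 0.25, 0.15, 0.3)
    seq_length: int = 1137
    area_count: int = 6
    dispersal_rate: float = 0.1  # events / lineage / Ma
    extinction_rate: float = 0.3
    within_species_depth: float = 0.15  # Ma, crown depth bound for haplotypes
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        for name in ("birth_rate", "death_rate", "clock_rate_mean",
                     "dispersal_rate", "extinction_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.birth_rate <= self.death_rate:
            raise ValueError("birth_rate must exceed death_rate")
        if self.clock_model not in ("strict", "lognormal-relaxed"):
            raise ValueError("clock_model must be 'strict' or 'lognormal-relaxed'")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


@dataclass
class BioEvent:
    """One event of the biogeographic history, in node-age coordinates (Ma).

    For cladogenetic events (vicariance/duplication) ``inherited`` maps each
    daughter node label to the area set it inherits, so the history can be
    replayed from the event list alone.
    """

    kind: str  # dispersal | extinction | vicariance | duplication
    node: str  # tip/internal label of the branch's child node (or the node itself)
    time: float  # Ma before present
    areas: tuple[str, ...]
    inherited: dict[str, tuple[str, ...]] | None = None

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrueHistory:
    """Ground truth bundled across the three generators."""

    tree: dendropy.Tree
    node_areas: dict[str, frozenset[str]]  # node label -> true area set
    events: list[BioEvent]
    tip_areas: dict[str, frozenset[str]]
    tip_species: dict[str, str]
    branch_rates: dict[str, float] = field(default_factory=dict)
    root_set: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# dated birth-death species tree


def simulate_dated_tree(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> dendropy.Tree:
    """Simulate a dated, ultrametric birth-death tree with ``n_species`` tips.

    Forward Gillespie simulation from the root (two lineages).  The process
    is conditioned on reaching exactly ``n_species`` extant lineages: when the
    extant count first hits the target the stop time is drawn uniformly within
    the interval during which the count stays there, extinct lineages are
    pruned, and trees whose (pruned) root age exceeds ``root_age_bound`` are
    rejected.  Tip ages are exactly 0.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam, mu, n = config.birth_rate, config.death_rate, config.n_species
    for _ in range(max_attempts):
        result = _forward_bd_once(rng, lam, mu, n, config.root_age_bound)
        if result is not None:
            return result
    raise RuntimeError(
        f"no viable tree in {max_attempts} attempts; "
        "check birth/death rates and root_age_bound"
    )


def _forward_bd_once(rng, lam, mu, n, root_bound):
    """One forward birth-death attempt; returns a tree or None on rejection."""
    # per-lineage records; `kids` is (a, b) after speciation, "dead" after
    # extinction, "tip" if extant at the stop time.
    end = [np.nan, np.nan]
    kids: list = [None, None]
    alive = [0, 1]
    t = 0.0
    while True:
        k = len(alive)
        if k == 0:
            return None
        dt = rng.exponential(1.0 / (k * (lam + mu)))
        if k == n:
            # count just reached the target; stop uniformly before next event
            stop = t + rng.uniform(0.0, dt)
            break
        t += dt
        who = alive[rng.integers(k)]
        alive.remove(who)
        if mu == 0.0 or rng.random() < lam / (lam + mu):
            a, b = len(end), len(end) + 1
            end += [np.nan, np.nan]
            kids += [None, None]
            end[who] = t
            kids[who] = (a, b)
            alive += [a, b]
        else:
            end[who] = t
            kids[who] = "dead"
    for i in alive:
        end[i] = stop
        kids[i] = "tip"

    # prune to the extant part, suppressing unifurcations
    def prune(i):
        if kids[i] == "tip":
            return ("tip", stop)
        if kids[i] == "dead":
            return None
        a, b = kids[i]
        pa, pb = prune(a), prune(b)
        if pa is None:
            return pb
        if pb is None:
            return pa
        return ("node", end[i], pa, pb)

    top, other = prune(0), prune(1)
    if top is None or other is None:
        return None  # a root child clade died out: pruned tree loses the root
    if top[0] == "tip" and other[0] == "tip" and n != 2:
        return None
    root_node = ("node", 0.0, top, other)
    if stop > root_bound:
        return None

    counter = [0]

    def render(nd):
        if nd[0] == "tip":
            counter[0] += 1
            return f"S{counter[0]}"
        _, tsplit, a, b = nd
        return (
            f"({render(a)}:{a[1] - tsplit:.10g},"
            f"{render(b)}:{b[1] - tsplit:.10g})"
        )

    return read_tree(render(root_node) + ";")


def expand_haplotypes(
    species_tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Replace each species tip by a shallow clade of haplotype tips.

    Within-species divergences are drawn as a pure-birth subtree whose crown
    age is uniform on ``(0.2, 1) * within_species_depth`` Ma - deep species
    splits, shallow intraspecific coalescence.  Returns the expanded tree and
    the tip -> species map.
    """
    k = config.haplotypes_per_species
    tip_species: dict[str, str] = {}
    if k <= 1:
        for leaf in species_tree.leaf_node_iter():
            tip_species[leaf.taxon.label] = leaf.taxon.label
        return species_tree, tip_species

    def render(node) -> str:
        if node.is_leaf():
            sp = node.taxon.label
            stem = node.edge.length or 0.0
            labels = [f"{sp}_h{i + 1}" for i in range(k)]
            for lbl in labels:
                tip_species[lbl] = sp
            # crown depth stays shallow and inside the terminal branch
            depth = rng.uniform(0.2, 1.0) * min(
                config.within_species_depth, 0.5 * stem
            )
            frag = _yule_clade_newick(labels, depth, rng)
            return f"{frag}:{stem - depth:.10g}"
        parts = [render(c) for c in node.child_nodes()]
        stem = node.edge.length
        suffix = f":{stem:.10g}" if stem is not None else ""
        return f"({','.join(parts)}){suffix}"

    newick = render(species_tree.seed_node) + ";"
    return read_tree(newick), tip_species


def _yule_clade_newick(labels: list[str], depth: float, rng) -> str:
    """Random-ultrametric clade over labels with crown age `depth`."""
    if len(labels) == 1:
        return labels[0]
    # coalescent-style random joins with node ages spread uniformly below depth
    ages = sorted(rng.uniform(0.0, depth, size=len(labels) - 1))
    ages[-1] = depth
    items: list[tuple[str, float]] = [(lbl, 0.0) for lbl in labels]
    for age in ages:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (sa, ta) = items[i]
        (sb, tb) = items[j]
        merged = (f"({sa}:{age - ta:.10g},{sb}:{age - tb:.10g})", age)
        items = [it for idx, it in enumerate(items) if idx not in (i, j)]
        items.append(merged)
    return items[0][0]


# ---------------------------------------------------------------------------
# biogeographic history


def default_area_system(area_count: int) -> AreaSystem:
    """Path-adjacent endemic areas a, b, c, ... (a coastal chain)."""
    labels = [chr(ord("a") + i) for i in range(area_count)]
    adjacency = [(labels[i], labels[i + 1]) for i in range(area_count - 1)]
    return AreaSystem(labels, adjacency)


def simulate_biogeography(
    tree: dendropy.Tree,
    areas: AreaSystem,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    root_set: frozenset[str] | None = None,
) -> TrueHistory:
    """Simulate dispersal/extinction along branches and splits at nodes.

    Along each branch, a lineage occupying area set S disperses into an
    unoccupied area adjacent to S at total rate ``dispersal_rate`` (target
    uniform among candidates) and loses one occupied area at total rate
    ``extinction_rate`` whenever ``|S| > 1`` (ranges never empty).  At each
    node a multi-area set splits by vicariance into a uniformly random
    disjoint bipartition; a single-area set duplicates into both daughters.
    """
    config.validate()
    if not areas.is_connected():
        raise ValueError("area adjacency graph must be connected")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ages = _label_and_age(tree)
    if root_set is None:
        root_set = frozenset([areas.labels[rng.integers(len(areas.labels))]])
    if not root_set <= set(areas.labels):
        raise ValueError("root_set contains unknown areas")

    events: list[BioEvent] = []
    node_areas: dict[str, frozenset[str]] = {}

    def branch_evolve(state: frozenset[str], t_start: float, t_end: float, label: str):
        """Evolve from age t_start down to t_end (t_start >= t_end)."""
        t = t_start
        s = set(state)
        while True:
            can_disperse = bool(_dispersal_targets(s, areas))
            rate_d = config.dispersal_rate if can_disperse else 0.0
            rate_e = config.extinction_rate if len(s) > 1 else 0.0
            total = rate_d + rate_e
            if total == 0.0:
                break
            dt = rng.exponential(1.0 / total)
            if t - dt < t_end:
                break
            t -= dt
            if rng.random() < rate_d / total:
                targets = sorted(_dispersal_targets(s, areas))
                gain = targets[rng.integers(len(targets))]
                s.add(gain)
                events.append(BioEvent("dispersal", label, t, (gain,)))
            else:
                lose = sorted(s)[rng.integers(len(s))]
                s.discard(lose)
                events.append(BioEvent("extinction", label, t, (lose,)))
        return frozenset(s)

    root = tree.seed_node
    node_areas[root.label] = root_set

    for node in tree.preorder_node_iter():
        label = node.label if not node.is_leaf() else node.taxon.label
        state = node_areas[label]
        if node.is_leaf():
            continue
        left, right = node.child_nodes()
        llabel = left.taxon.label if left.is_leaf() else left.label
        rlabel = right.taxon.label if right.is_leaf() else right.label
        if len(state) > 1:
            sl, sr = _random_bipartition(state, rng)
            kind = "vicariance"
        else:
            sl = sr = state
            kind = "duplication"
        events.append(
            BioEvent(
                kind, label, ages[node], tuple(sorted(state)),
                inherited={llabel: tuple(sorted(sl)), rlabel: tuple(sorted(sr))},
            )
        )
        for child, clabel, inherited in ((left, llabel, sl), (right, rlabel, sr)):
            node_areas[clabel] = branch_evolve(
                inherited, ages[node], ages[child], clabel
            )

    tip_areas = {
        leaf.taxon.label: node_areas[leaf.taxon.label]
        for leaf in tree.leaf_node_iter()
    }
    tip_species = {lbl: lbl for lbl in tip_areas}
    events.sort(key=lambda e: -e.time)
    return TrueHistory(
        tree=tree,
        node_areas=node_areas,
        events=events,
        tip_areas=tip_areas,
        tip_species=tip_species,
        root_set=root_set,
    )


def _dispersal_targets(s: set[str], areas: AreaSystem) -> set[str]:
    out: set[str] = set()
    for a in s:
        out |= set(areas.neighbors(a))
    return out - s


def _random_bipartition(state: frozenset[str], rng) -> tuple[frozenset[str], frozenset[str]]:
    """Uniform over ordered disjoint bipartitions into nonempty subsets."""
    items = sorted(state)
    while True:
        mask = rng.integers(0, 2, size=len(items))
        if 0 < mask.sum() < len(items):
            left = frozenset(a for a, m in zip(items, mask) if m)
            return left, frozenset(state) - left


def _label_and_age(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Assign stable labels to internal nodes and return node ages."""
    from .trees import node_ages

    ages = node_ages(tree)
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"N{i}"
            i += 1
        else:
            i += 1
    return ages


# ---------------------------------------------------------------------------
# alignment


def simulate_alignment(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], dict[str, float]]:
    """Evolve a coding alignment down a dated tree under HKY.

    Returns ``(records, branch_rates)`` where records are ``(label,
    sequence)`` pairs ordered by sorted tip label and ``branch_rates`` maps
    each non-root node label to the true substitution rate of the branch
    above it.  The root sequence is drawn codon-by-codon from the stationary
    base frequencies, rejecting vertebrate-mitochondrial stop codons in
    frame 0.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = HKYModel(config.kappa, np.asarray(config.base_freqs))
    _label_and_age(tree)
    from .trees import node_ages as _ages

    ages = _ages(tree)
    root_states = _sample_root_coding(rng, config.seq_length, model.freqs)

    branch_rates: dict[str, float] = {}
    seqs: dict[str, np.ndarray] = {}

    def rate_for_branch() -> float:
        if config.clock_model == "strict":
            return config.clock_rate_mean
        m, sd = config.clock_rate_mean, config.relaxed_sd
        sigma2 = np.log1p((sd / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))

    states = {tree.seed_node: root_states}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        label = node.taxon.label if node.is_leaf() else node.label
        rate = rate_for_branch()
        branch_rates[label] = rate
        dist = rate * (ages[node.parent_node] - ages[node])
        P = model.transition_matrix(dist)
        parent_states = states[node.parent_node]
        states[node] = _evolve(parent_states, P, rng)
        if node.is_leaf():
            seqs[label] = states[node]

    alphabet = np.array(list("ACGT"))
    records = [
        (lbl, "".join(alphabet[seqs[lbl]])) for lbl in sorted(seqs)
    ]
    return records, branch_rates


def _evolve(parent: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent.shape[0])
    child = np.empty_like(parent)
    for s in range(4):
        mask = parent == s
        if mask.any():
            child[mask] = np.searchsorted(cum[s], u[mask], side="right")
    np.clip(child, 0, 3, out=child)
    return child


def _sample_root_coding(rng, length: int, freqs: np.ndarray) -> np.ndarray:
    """IID stationary sequence with no in-frame stop codon (frame 0)."""
    states = rng.choice(4, size=length, p=freqs)
    alphabet = "ACGT"
    for c0 in range(0, length - 2, 3):
        while True:
            codon = "".join(alphabet[s] for s in states[c0 : c0 + 3])
            if codon not in VERTEBRATE_MITO_STOPS:
                break
            states[c0 : c0 + 3] = rng.choice(4, size=3, p=freqs)
    return states


# ---------------------------------------------------------------------------
# bundled dataset


def simulate_dataset(
    config: SimulationConfig,
    areas: AreaSystem | None = None,
    root_set: frozenset[str] | None = None,
) -> tuple[TrueHistory, list[tuple[str, str]]]:
    """Run all three generators with one seed; returns (history, alignment)."""
    rng = np.random.default_rng(config.seed)
    species_tree = simulate_dated_tree(config, rng)
    tree, tip_species = expand_haplotypes(species_tree, config, rng)
    if areas is None:
        areas = default_area_system(config.area_count)
    history = simulate_biogeography(species_tree, areas, config, rng, root_set)
    records, branch_rates = simulate_alignment(tree, config, rng)
    history.branch_rates = branch_rates
    history.tip_species = tip_species
    # haplotype tips inherit their species' areas
    history.tip_areas = {
        tip: history.node_areas[sp] for tip, sp in tip_species.items()
    }
    history.tree = tree
    return history, records


def write_dataset(history: TrueHistory, records, outdir, seed: int) -> dict[str, str]:
    """Write FASTA, Newick, tip tables and the JSON event log, keyed by seed."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    fasta = os.path.join(outdir, f"alignment_seed{seed}.fasta")
    with open(fasta, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n{seq}\n")
    paths["fasta"] = fasta
    nwk = os.path.join(outdir, f"tree_seed{seed}.nwk")
    with open(nwk, "w") as fh:
        fh.write(history.tree.as_string(schema="newick", suppress_rooting=True))
    paths["tree"] = nwk
    tips = os.path.join(outdir, f"tip_areas_seed{seed}.tsv")
    with open(tips, "w") as fh:
        for tip in sorted(history.tip_areas):
            fh.write(f"{tip}\t{','.join(sorted(history.tip_areas[tip]))}\n")
    paths["tip_areas"] = tips
    spec_table = os.path.join(outdir, f"tip_species_seed{seed}.tsv")
    with open(spec_table, "w") as fh:
        for tip in sorted(history.tip_species):
            fh.write(f"{tip}\t{history.tip_species[tip]}\n")
    paths["tip_species"] = spec_table
    events = os.path.join(outdir, f"events_seed{seed}.json")
    with open(events, "w") as fh:
        json.dump([e.to_json() for e in history.events], fh, indent=1)
    paths["events"] = events
    return paths
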