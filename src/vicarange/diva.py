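"""Event-based dispersal-vicariance ancestral-area reconstruction.

Classic DIVA cost structure made explicit: vicariance (a disjoint bipartition
of the ancestral set between the daughters) and duplication (a single-area
ancestor inherited by both daughters) are free; each area gained along a
branch costs one dispersal, each area lost costs one extinction.  A Sankoff
dynamic program over all nonempty area sets of size <= maxareas yields the
minimal total cost and, via an up/down pass, *every* equally optimal
ancestral set per node.  Adjacency is deliberately not part of the cost
(classic DIVA is adjacency-blind); it is used downstream by the
extinction-inference stage.

Area sets are bitmasks over at most 16 areas, keeping the subset DP exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import dendropy
import networkx as nx
import numpy as np

from .trees import IndexedTree

__all__ = [
    "AreaSystem",
    "AncestralAreaReconstruction",
    "diva_optimize",
    "diva_exhaustive",
    "sdiva_frequencies",
    "maxareas_sensitivity",
    "read_tip_areas",
    "read_adjacency",
]

MAX_AREAS = 16


@dataclass
class AreaSystem:
    """Discrete areas with a symmetric, irreflexive adjacency relation."""

    labels: list[str]
    adjacency: list[tuple[str, str]]
    centroids: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("area labels must be unique")
        if len(self.labels) > MAX_AREAS:
            raise ValueError(f"at most {MAX_AREAS} areas supported")
        known = set(self.labels)
        for a, b in self.adjacency:
            if a == b:
                raise ValueError(f"self-adjacency {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"adjacency references unknown area: {(a, b)}")
        self._index = {a: i for i, a in enumerate(self.labels)}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.adjacency)
        return g

    def neighbors(self, area: str) -> set[str]:
        out = set()
        for a, b in self.adjacency:
            if a == area:
                out.add(b)
            elif b == area:
                out.add(a)
        return out

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph())

    def mask(self, areas) -> int:
        m = 0
        for a in areas:
            m |= 1 << self._index[a]
        return m

    def unmask(self, mask: int) -> frozenset[str]:
        return frozenset(
            a for a, i in self._index.items() if mask >> i & 1
        )


@dataclass
class NodeReconstruction:
    clade: frozenset[str]  # tip labels defining the node
    optimal_sets: list[frozenset[str]]
    frequencies: list[float]  # conditional on the clade; sum to 1
    clade_support: float = 1.0

    def weighted_frequencies(self) -> list[float]:
        return [f * self.clade_support for f in self.frequencies]


@dataclass
class AncestralAreaReconstruction:
    nodes: dict[frozenset[str], NodeReconstruction]
    total_cost: float
    maxareas: int
    event_counts: dict[str, float] = field(default_factory=dict)

    def node_by_tips(self, tips) -> NodeReconstruction:
        return self.nodes[frozenset(tips)]


def read_tip_areas(path: str) -> dict[str, frozenset[str]]:
    """Tab-separated ``tip<TAB>a,b,c`` table."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tip, areas = line.split("\t")
            out[tip] = frozenset(areas.split(","))
    return out


def read_adjacency(path: str) -> list[tuple[str, str]]:
    """Whitespace-separated pairs, one adjacency per line."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()
            pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# dynamic program


def _popcount(x: int) -> int:
    return bin(x).count("1")


def _candidate_masks(n_areas: int, maxareas: int) -> list[int]:
    return [
        m for m in range(1, 1 << n_areas) if _popcount(m) <= maxareas
    ]


def _inheritances(mask: int, allow_widespread_sympatry: bool):
    """Yield (left, right) inherited masks for an ancestor with set `mask`."""
    if _popcount(mask) == 1:
        yield (mask, mask)
        return
    bits = [1 << i for i in range(MAX_AREAS) if mask >> i & 1]
    k = len(bits)
    # ordered disjoint bipartitions into nonempty subsets
    for assign in range(1, (1 << k) - 1):
        left = 0
        for j in range(k):
            if assign >> j & 1:
                left |= bits[j]
        yield (left, mask ^ left)
    if allow_widespread_sympatry:
        # one daughter keeps the full range, the other any nonempty subset
        for sub in range(1, 1 << k):
            s = 0
            for j in range(k):
                if sub >> j & 1:
                    s |= bits[j]
            yield (mask, s)
            if s != mask:
                yield (s, mask)


def diva_optimize(
    tree: dendropy.Tree,
    tip_areas: dict[str, frozenset[str]],
    maxareas: int,
    areas: AreaSystem | None = None,
    allow_widespread_sympatry: bool = False,
) -> AncestralAreaReconstruction:
    """Minimum-event dispersal-vicariance reconstruction.

    Returns every cost-optimal ancestral area set per internal node (uniform
    frequencies within a node) together with the global minimal event cost.
    """
    itree = IndexedTree(tree)
    if areas is None:
        labels = sorted(set().union(*tip_areas.values()))
        areas = AreaSystem(labels, [])
    for tip in itree.tip_labels:
        if tip not in tip_areas or not tip_areas[tip]:
            raise ValueError(f"tip {tip!r} has no area assignment")
        unknown = tip_areas[tip] - set(areas.labels)
        if unknown:
            raise ValueError(f"tip {tip!r} has unknown areas {sorted(unknown)}")
    largest_tip = max(len(tip_areas[t]) for t in itree.tip_labels)
    if not (1 <= maxareas <= len(areas.labels)):
        raise ValueError("maxareas must be in 1..|areas|")
    if maxareas < largest_tip:
        raise ValueError(
            f"maxareas={maxareas} below largest tip area set ({largest_tip})"
        )

    n_areas = len(areas.labels)
    cands = _candidate_masks(n_areas, maxareas)
    cand_index = {m: i for i, m in enumerate(cands)}
    ncand = len(cands)
    INF = np.inf

    # symmetric-difference branch cost between any inherited and child set
    diff = np.empty((ncand, ncand))
    for i, a in enumerate(cands):
        for j, b in enumerate(cands):
            diff[i, j] = _popcount(a ^ b)

    inh = {
        m: list(_inheritances(m, allow_widespread_sympatry)) for m in cands
    }

    # up[v][D]: min cost of v's subtree when v's set is D (excl. v's stem)
    up = np.full((itree.n_nodes, ncand), INF)
    for t in range(itree.n_tips):
        mask = areas.mask(tip_areas[itree.tip_labels[t]])
        up[t, cand_index[mask]] = 0.0
    # m_in[v][S]: min over child sets C of up[v][C] + |C ^ S|
    m_in = np.full((itree.n_nodes, ncand), INF)

    def fill_m_in(v: int) -> None:
        m_in[v] = np.min(up[v][None, :] + diff, axis=1)

    for t in range(itree.n_tips):
        fill_m_in(t)
    for v in itree.postorder_internal:
        l, r = itree.children[v - itree.n_tips]
        for Di, D in enumerate(cands):
            best = INF
            for sl, sr in inh[D]:
                c = m_in[l][cand_index[sl]] + m_in[r][cand_index[sr]]
                if c < best:
                    best = c
            up[v, Di] = best
        fill_m_in(v)

    total_cost = float(up[itree.root].min())

    # down[v][D]: min cost of the rest of the tree when v's set is D
    down = np.full((itree.n_nodes, ncand), INF)
    down[itree.root] = 0.0
    for v in itree.postorder_internal[::-1]:
        l, r = itree.children[v - itree.n_tips]
        # min over D and inheritance of down[v][D] + cost to other child
        best_l = np.full(ncand, INF)  # indexed by inherited set for left
        best_r = np.full(ncand, INF)
        for Di, D in enumerate(cands):
            base = down[v, Di]
            if not np.isfinite(base):
                continue
            for sl, sr in inh[D]:
                cl = base + m_in[r][cand_index[sr]]
                if cl < best_l[cand_index[sl]]:
                    best_l[cand_index[sl]] = cl
                cr = base + m_in[l][cand_index[sl]]
                if cr < best_r[cand_index[sr]]:
                    best_r[cand_index[sr]] = cr
        down[l] = np.min(best_l[None, :] + diff.T, axis=1)
        down[r] = np.min(best_r[None, :] + diff.T, axis=1)

    nodes: dict[frozenset[str], NodeReconstruction] = {}
    for v in itree.postorder_internal:
        tot = up[v] + down[v]
        best = tot.min()
        opt = [areas.unmask(cands[i]) for i in np.flatnonzero(tot <= best + 1e-9)]
        clade = itree.clade_labels(v)
        nodes[clade] = NodeReconstruction(
            clade=clade,
            optimal_sets=opt,
            frequencies=[1.0 / len(opt)] * len(opt),
        )
    return AncestralAreaReconstruction(
        nodes=nodes, total_cost=total_cost, maxareas=maxareas
    )


def diva_exhaustive(
    tree: dendropy.Tree,
    tip_areas: dict[str, frozenset[str]],
    maxareas: int,
    areas: AreaSystem | None = None,
    allow_widespread_sympatry: bool = False,
) -> AncestralAreaReconstruction:
    """Brute-force reference: enumerate every assignment of ancestral sets.

    Exponential in the number of internal nodes; use for <= ~5 tips and
    <= 3 areas.  Independent of the dynamic program above.
    """
    itree = IndexedTree(tree)
    if areas is None:
        labels = sorted(set().union(*tip_areas.values()))
        areas = AreaSystem(labels, [])
    n_areas = len(areas.labels)
    cands = _candidate_masks(n_areas, maxareas)
    internals = list(itree.postorder_internal)
    tip_mask = {
        t: areas.mask(tip_areas[itree.tip_labels[t]]) for t in range(itree.n_tips)
    }

    def node_cost(D: int, cl: int, cr: int) -> float:
        best = np.inf
        for sl, sr in _inheritances(D, allow_widespread_sympatry):
            c = _popcount(sl ^ cl) + _popcount(sr ^ cr)
            if c < best:
                best = c
        return best

    from itertools import product as iproduct

    best_cost = np.inf
    per_node_best: dict[int, dict[int, float]] = {v: {} for v in internals}
    for combo in iproduct(cands, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        cost = 0.0
        for v in internals:
            l, r = itree.children[v - itree.n_tips]
            cl = assign[l] if l in assign else tip_mask[l]
            cr = assign[r] if r in assign else tip_mask[r]
            cost += node_cost(assign[v], cl, cr)
        best_cost = min(best_cost, cost)
        for v in internals:
            d = per_node_best[v]
            m = assign[v]
            if m not in d or cost < d[m]:
                d[m] = cost
    nodes = {}
    for v in internals:
        opt = [
            areas.unmask(m)
            for m, c in sorted(per_node_best[v].items())
            if c <= best_cost + 1e-9
        ]
        clade = itree.clade_labels(v)
        nodes[clade] = NodeReconstruction(
            clade=clade,
            optimal_sets=opt,
            frequencies=[1.0 / len(opt)] * len(opt),
        )
    return AncestralAreaReconstruction(
        nodes=nodes, total_cost=float(best_cost), maxareas=maxareas
    )


# ---------------------------------------------------------------------------
# S-DIVA over tree samples


def sdiva_frequencies(
    trees: list[dendropy.Tree],
    tip_areas: dict[str, frozenset[str]],
    maxareas: int,
    areas: AreaSystem | None = None,
) -> AncestralAreaReconstruction:
    """Average per-node optimal-set frequencies over a tree sample.

    Nodes are matched across trees by their tip bipartition.  Within each
    tree the equally parsimonious sets of a node get uniform weight; across
    trees the node's conditional frequencies are averaged over the trees
    containing the bipartition, and ``clade_support`` records the fraction
    of trees containing it (so support-weighted frequencies sum to the
    occurrence fraction, as in S-DIVA summaries).
    """
    if not trees:
        raise ValueError("empty tree sample")
    tipsets = {frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees}
    if len(tipsets) != 1:
        raise ValueError("all trees must share one tip set")
    acc: dict[frozenset[str], dict[frozenset[str], float]] = {}
    seen: dict[frozenset[str], int] = {}
    total_costs = []
    for tree in trees:
        rec = diva_optimize(tree, tip_areas, maxareas, areas)
        total_costs.append(rec.total_cost)
        for clade, nr in rec.nodes.items():
            seen[clade] = seen.get(clade, 0) + 1
            slot = acc.setdefault(clade, {})
            for s, f in zip(nr.optimal_sets, nr.frequencies):
                slot[s] = slot.get(s, 0.0) + f
    n = len(trees)
    nodes = {}
    for clade, slot in acc.items():
        sets = sorted(slot, key=lambda s: sorted(s))
        freqs = [slot[s] / seen[clade] for s in sets]
        nodes[clade] = NodeReconstruction(
            clade=clade,
            optimal_sets=list(sets),
            frequencies=freqs,
            clade_support=seen[clade] / n,
        )
    return AncestralAreaReconstruction(
        nodes=nodes, total_cost=float(np.mean(total_costs)), maxareas=maxareas
    )


# ---------------------------------------------------------------------------
# maxareas sensitivity


@dataclass
class SensitivityReport:
    settings: list[int]
    rejected: dict[int, str]
    agree: dict[frozenset[str], bool]
    alternatives: dict[frozenset[str], dict[int, list[frozenset[str]]]]

    def all_agree(self) -> bool:
        return all(self.agree.values())


def maxareas_sensitivity(
    tree: dendropy.Tree,
    tip_areas: dict[str, frozenset[str]],
    maxareas_values: list[int],
    areas: AreaSystem | None = None,
) -> SensitivityReport:
    """Run DIVA under several maxareas settings and diff the optimal sets."""
    if len(maxareas_values) < 2:
        raise ValueError("need at least two maxareas settings")
    largest_tip = max(len(v) for v in tip_areas.values())
    rejected: dict[int, str] = {}
    runs: dict[int, AncestralAreaReconstruction] = {}
    for k in maxareas_values:
        if k < largest_tip:
            rejected[k] = f"below largest tip area-set size {largest_tip}"
            continue
        runs[k] = diva_optimize(tree, tip_areas, k, areas)
    if not runs:
        raise ValueError("every maxareas setting was rejected")
    settings = sorted(runs)
    clades = list(runs[settings[0]].nodes)
    agree: dict[frozenset[str], bool] = {}
    alternatives: dict[frozenset[str], dict[int, list[frozenset[str]]]] = {}
    for clade in clades:
        per = {k: sorted(runs[k].nodes[clade].optimal_sets, key=sorted) for k in settings}
        first = per[settings[0]]
        same = all(per[k] == first for k in settings)
        agree[clade] = same
        if not same:
            alternatives[clade] = per
    return SensitivityReport(
        settings=settings, rejected=rejected, agree=agree, alternatives=alternatives
    )
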