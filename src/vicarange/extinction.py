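"""Vicariance-versus-dispersal classification of nodes and extinction dating.

The rule: if the two daughter ranges at a node overlap, or some area of one
is directly adjacent (on the area graph) to some area of the other, the
split needs no range loss and is called vicariance.  Otherwise the split
implies an earlier dispersal followed by local extinction in the areas that
geographically intervene between the daughter ranges; those areas are the
interiors of all shortest adjacency paths between the two ranges, and each
postulated extinction is dated to the stem branch of the node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import dendropy
import networkx as nx

from .diva import AncestralAreaReconstruction, AreaSystem
from .trees import IndexedTree, node_ages

__all__ = [
    "EventClassification",
    "ExtinctionEvent",
    "classify_node",
    "classify_tree",
    "intervening_areas",
    "date_extinctions",
]

VICARIANCE = "vicariance"
DISPERSAL_EXT = "dispersal_with_extinction"
AMBIGUOUS = "ambiguous"


@dataclass
class EventClassification:
    node: frozenset[str]  # clade (tip labels) identifying the node
    verdict: str  # vicariance | dispersal_with_extinction | ambiguous
    left_set: frozenset[str]
    right_set: frozenset[str]
    overlap: frozenset[str] = frozenset()
    intervening: frozenset[str] = frozenset()
    per_reconstruction: list["EventClassification"] = field(default_factory=list)


@dataclass
class ExtinctionEvent:
    area: str
    older: float  # Ma
    younger: float  # Ma
    node: frozenset[str]

    def __post_init__(self):
        if not (self.older >= self.younger >= 0):
            raise ValueError("require older >= younger >= 0")


def _check_known(s: frozenset[str], areas: AreaSystem) -> None:
    unknown = s - set(areas.labels)
    if unknown:
        raise ValueError(f"unknown areas {sorted(unknown)}")


def classify_node(
    left_set: frozenset[str],
    right_set: frozenset[str],
    areas: AreaSystem,
    node: frozenset[str] = frozenset(),
    single_path: bool = False,
) -> EventClassification:
    """Classify one daughter-range pair as vicariance or dispersal+extinction."""
    left_set, right_set = frozenset(left_set), frozenset(right_set)
    if not left_set or not right_set:
        raise ValueError("daughter area sets must be nonempty")
    _check_known(left_set, areas)
    _check_known(right_set, areas)
    overlap = left_set & right_set
    if overlap:
        return EventClassification(node, VICARIANCE, left_set, right_set, overlap)
    g = areas.graph()
    if any(g.has_edge(a, b) for a in left_set for b in right_set):
        return EventClassification(node, VICARIANCE, left_set, right_set)
    inter = intervening_areas(left_set, right_set, areas, single_path=single_path)
    return EventClassification(
        node, DISPERSAL_EXT, left_set, right_set, intervening=inter
    )


def intervening_areas(
    A: frozenset[str],
    B: frozenset[str],
    areas: AreaSystem,
    single_path: bool = False,
) -> frozenset[str]:
    """Interior areas of the shortest adjacency paths between ranges A and B.

    The A-to-B distance is the minimum over area pairs of the shortest-path
    edge count; by default the union of the interiors of *all* shortest
    paths achieving that distance is returned (``single_path`` keeps one
    path only, for minimal-extinction counting).
    """
    A, B = frozenset(A), frozenset(B)
    if not A or not B:
        raise ValueError("ranges must be nonempty")
    if A & B:
        raise ValueError("ranges overlap; nothing intervenes")
    g = areas.graph()
    if any(g.has_edge(a, b) for a in A for b in B):
        raise ValueError("ranges are adjacent; nothing intervenes")
    best = None
    pairs = []
    for a, b in product(sorted(A), sorted(B)):
        try:
            d = nx.shortest_path_length(g, a, b)
        except nx.NetworkXNoPath:
            continue
        if best is None or d < best:
            best = d
            pairs = [(a, b)]
        elif d == best:
            pairs.append((a, b))
    if best is None:
        return frozenset()  # disconnected: no path, nothing to name
    interior: set[str] = set()
    for a, b in pairs:
        if single_path:
            path = nx.shortest_path(g, a, b)
            interior |= set(path[1:-1])
            break
        for path in nx.all_shortest_paths(g, a, b):
            interior |= set(path[1:-1])
    return frozenset(interior)


def classify_tree(
    reconstruction: AncestralAreaReconstruction,
    tree: dendropy.Tree,
    areas: AreaSystem,
    tip_areas: dict[str, frozenset[str]],
    single_path: bool = False,
) -> list[EventClassification]:
    """Classify every internal node, surfacing ambiguity across equally
    optimal DIVA reconstructions instead of averaging it away."""
    itree = IndexedTree(tree)

    def sets_for(node_idx: int) -> list[frozenset[str]]:
        if node_idx < itree.n_tips:
            return [tip_areas[itree.tip_labels[node_idx]]]
        return reconstruction.nodes[itree.clade_labels(node_idx)].optimal_sets

    out: list[EventClassification] = []
    for v in itree.postorder_internal:
        l, r = itree.children[v - itree.n_tips]
        clade = itree.clade_labels(v)
        combos = [
            classify_node(sl, sr, areas, node=clade, single_path=single_path)
            for sl in sets_for(l)
            for sr in sets_for(r)
        ]
        verdicts = {c.verdict for c in combos}
        if len(verdicts) == 1:
            chosen = combos[0]
            if len(combos) > 1:
                # merge intervening areas across agreeing reconstructions
                inter = frozenset().union(*(c.intervening for c in combos))
                chosen = EventClassification(
                    clade, chosen.verdict, chosen.left_set, chosen.right_set,
                    overlap=chosen.overlap, intervening=inter,
                    per_reconstruction=combos,
                )
            out.append(chosen)
        else:
            out.append(
                EventClassification(
                    clade, AMBIGUOUS, combos[0].left_set, combos[0].right_set,
                    per_reconstruction=combos,
                )
            )
    return out


def date_extinctions(
    classifications: list[EventClassification],
    dated_tree: dendropy.Tree,
    include_ambiguous: bool = False,
) -> list[ExtinctionEvent]:
    """Date each postulated extinction onto the stem branch of its node.

    For a node at age ``t`` whose parent sits at age ``T``, every intervening
    area yields one event on ``[T, t]``; the root uses its own age as the
    older bound.  Ambiguous nodes contribute only with ``include_ambiguous``
    (then the union over per-reconstruction intervening sets is used).
    """
    itree = IndexedTree(dated_tree)
    if not any(l is not None for l in itree.edge_length[: itree.n_tips]):
        raise ValueError("tree has no branch lengths; cannot date events")
    ages = itree.ages_from_edges()
    clade_to_idx = {itree.clade_labels(v): v for v in itree.postorder_internal}
    events: list[ExtinctionEvent] = []
    for cls in classifications:
        if cls.verdict == VICARIANCE:
            continue
        if cls.verdict == AMBIGUOUS and not include_ambiguous:
            continue
        inter = cls.intervening
        if cls.verdict == AMBIGUOUS:
            inter = frozenset().union(
                *(c.intervening for c in cls.per_reconstruction)
            )
        v = clade_to_idx[cls.node]
        younger = float(ages[v])
        parent = itree.parent[v]
        older = float(ages[parent]) if parent >= 0 else float(ages[v])
        if parent < 0:
            older = float(ages[v])
        for area in sorted(inter):
            events.append(ExtinctionEvent(area, older, younger, cls.node))
    return events
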