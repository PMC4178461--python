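"""The breaking phase: cut amplicon chains inside OTUs at abundance valleys.

Single-linkage growth can chain two species through a path of rare
intermediate amplicons.  Such chains show up on the capture tree as an
abundance profile that descends from a high-abundance *peak*, passes
through a minimum, and rises again towards a second peak (a *valley*).
Only amplicons with at least ``peak_min_abundance`` copies (default 100)
are considered peaks; a valley is cut when the ratio of the secondary
peak's abundance to the valley minimum reaches ``valley_ratio`` (default
50).  OTUs without two peaks are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .align import (
    DEFAULT_PENALTIES,
    PenaltySystem,
    count_differences,
    transform_scoring,
)
from .cluster import ClusteringResult, Otu, compute_stats
from .io import Amplicon

__all__ = [
    "BreakerParams",
    "ValleyVerdict",
    "find_peaks",
    "evaluate_path",
    "break_otu",
    "refine",
]


@dataclass(frozen=True)
class BreakerParams:
    peak_min_abundance: int = 100
    valley_ratio: float = 50.0

    def __post_init__(self) -> None:
        if self.peak_min_abundance < 1:
            raise ValueError("peak_min_abundance must be >= 1")
        if self.valley_ratio <= 1:
            raise ValueError("valley_ratio must be > 1")


@dataclass(frozen=True)
class ValleyVerdict:
    """Assessment of the capture-tree path between two peaks.

    ``valley_min`` is the lowest-abundance member strictly inside the path
    (earliest along the path from the primary peak on ties); ``breakable``
    requires an interior member strictly below the secondary peak's
    abundance and a secondary-to-minimum ratio of at least ``valley_ratio``.
    """

    primary_peak: Amplicon
    secondary_peak: Amplicon
    path: tuple[Amplicon, ...]
    valley_min: Optional[Amplicon]
    ratio: float
    breakable: bool


def _capture_tree(otu: Otu) -> nx.Graph:
    tree = nx.Graph()
    tree.add_nodes_from(m.identifier for m in otu.members)
    tree.add_weighted_edges_from(otu.capture_edges, weight="differences")
    return tree


def find_peaks(otu: Otu, params: Optional[BreakerParams] = None) -> list[Amplicon]:
    """Members abundant enough to count as peaks, most abundant first.

    Ties are broken by capture order (the order of ``otu.members``).
    """
    if params is None:
        params = BreakerParams()
    peaks = [m for m in otu.members if m.abundance >= params.peak_min_abundance]
    order = {m.identifier: i for i, m in enumerate(otu.members)}
    peaks.sort(key=lambda m: (-m.abundance, order[m.identifier]))
    return peaks


def evaluate_path(
    otu: Otu,
    primary: Amplicon,
    secondary: Amplicon,
    params: Optional[BreakerParams] = None,
) -> ValleyVerdict:
    """Judge the unique capture-tree path from the primary to the secondary peak."""
    if params is None:
        params = BreakerParams()
    if primary.abundance < secondary.abundance:
        raise ValueError("primary peak must be at least as abundant as secondary")
    members = {m.identifier: m for m in otu.members}
    if primary.identifier not in members or secondary.identifier not in members:
        raise ValueError("both peaks must belong to the OTU")
    tree = _capture_tree(otu)
    path_ids = nx.shortest_path(tree, primary.identifier, secondary.identifier)
    path = tuple(members[i] for i in path_ids)
    interior = path[1:-1]
    if not interior:
        return ValleyVerdict(primary, secondary, path, None, 0.0, False)
    valley_min = min(interior, key=lambda m: m.abundance)  # earliest on ties
    ratio = secondary.abundance / valley_min.abundance
    breakable = (
        valley_min.abundance < secondary.abundance and ratio >= params.valley_ratio
    )
    return ValleyVerdict(primary, secondary, path, valley_min, ratio, breakable)


def _rebuild_component(
    otu: Otu, tree: nx.Graph, component: set[str], penalties: PenaltySystem
) -> Otu:
    """Re-root one post-cut component at its most abundant member."""
    members = {m.identifier: m for m in otu.members}
    order = {m.identifier: i for i, m in enumerate(otu.members)}
    component_members = sorted(component, key=order.__getitem__)
    seed_id = min(
        component_members, key=lambda i: (-members[i].abundance, order[i])
    )
    seed = members[seed_id]

    # Breadth-first re-rooting along the retained capture edges; generation
    # = depth from the new seed, sibling order by original capture order.
    generation_of = {seed_id: 0}
    new_members = [seed]
    capture_edges: list[tuple[str, str, int]] = []
    frontier = [seed_id]
    while frontier:
        next_frontier: list[str] = []
        for parent in frontier:
            children = sorted(
                (c for c in tree.neighbors(parent)
                 if c in component and c not in generation_of),
                key=order.__getitem__,
            )
            for child in children:
                generation_of[child] = generation_of[parent] + 1
                new_members.append(members[child])
                capture_edges.append(
                    (parent, child, tree.edges[parent, child]["differences"])
                )
                next_frontier.append(child)
        frontier = next_frontier

    seed_distance = {
        m.identifier: (
            0
            if m.identifier == seed_id
            else count_differences(seed.sequence, m.sequence, penalties)
        )
        for m in new_members
    }
    return Otu(
        seed=seed,
        members=new_members,
        generation_of=generation_of,
        capture_edges=capture_edges,
        seed_distance=seed_distance,
    )


def break_otu(
    otu: Otu,
    params: Optional[BreakerParams] = None,
    penalties: Optional[PenaltySystem] = None,
) -> list[Otu]:
    """Recursively split an OTU at its deepest breakable abundance valley.

    Among all peak pairs, the verdict with the largest ratio wins (ties:
    lower valley abundance, then capture order of the secondary peak); the
    capture-tree edge between the valley minimum and its neighbor on the
    primary-peak side is cut, the two components are re-rooted at their most
    abundant members, and each is searched again.  An OTU with fewer than
    two peaks is returned unchanged.
    """
    if params is None:
        params = BreakerParams()
    if penalties is None:
        penalties = DEFAULT_PENALTIES
    peaks = find_peaks(otu, params)
    if len(peaks) < 2:
        return [otu]
    order = {m.identifier: i for i, m in enumerate(otu.members)}
    best: Optional[ValleyVerdict] = None
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            verdict = evaluate_path(otu, peaks[i], peaks[j], params)
            if not verdict.breakable:
                continue
            key = (
                -verdict.ratio,
                verdict.valley_min.abundance,
                order[verdict.secondary_peak.identifier],
            )
            if best is None or key < best_key:
                best, best_key = verdict, key
    if best is None:
        return [otu]

    # Cut between the valley minimum and its primary-side path neighbor.
    path_ids = [m.identifier for m in best.path]
    valley_position = path_ids.index(best.valley_min.identifier)
    cut = (path_ids[valley_position - 1], path_ids[valley_position])
    tree = _capture_tree(otu)
    tree.remove_edge(*cut)
    pieces = [
        _rebuild_component(otu, tree, set(component), penalties)
        for component in nx.connected_components(tree)
    ]
    pieces.sort(
        key=lambda o: (-o.seed.abundance, order[o.seed.identifier])
    )
    result: list[Otu] = []
    for piece in pieces:
        result.extend(break_otu(piece, params, penalties))
    return result


def refine(
    result: ClusteringResult, params: Optional[BreakerParams] = None
) -> ClusteringResult:
    """Apply chain breaking to every OTU of a clustering.

    The output partition is a refinement of the input (splits only, never
    merges); statistics are recomputed per new OTU.  Idempotent: a second
    pass finds no remaining breakable valley.
    """
    if params is None:
        params = BreakerParams()
    penalties = transform_scoring(result.params.scoring)
    refined: list[Otu] = []
    for otu in result.otus:
        refined.extend(break_otu(otu, params, penalties))
    return ClusteringResult(otus=tuple(refined), params=result.params)
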