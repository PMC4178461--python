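"""The growth phase: iterative single-linkage clustering at local threshold d.

Amplicons are modelled as points in amplicon-space, where neighbors differ
by one edit (substitution, insertion or deletion).  An OTU is grown from a
seed: the seed captures every pool amplicon within d differences (generation
1); each captured subseed in turn captures remaining amplicons within d
(generation 2), and so on until a generation captures nothing.  Because a
subseed of generation g can only capture amplicons within (g+1)*d of the
seed, candidates further from the seed are skipped without alignment; the
candidate filter (sequence length and k-mer parity bounds) removes further
hopeless comparisons.  Both filters are lossless, so the resulting partition
is exactly the connected components of the <=d-difference graph: it does not
depend on the input order, and distinct OTUs are separated by at least d+1
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from ._encoding import encode_sequence
from .align import (
    PenaltySystem,
    ScoringSystem,
    _gotoh_ops,
    transform_scoring,
)
from .io import Amplicon, AmpliconPool
from .kmer import K_DEFAULT, build_profile, difference_lower_bound

__all__ = [
    "ClusteringParams",
    "OtuStats",
    "Otu",
    "ClusteringResult",
    "swarm_cluster",
    "grow_otu",
    "generation_filter",
    "compute_stats",
]


@dataclass(frozen=True)
class ClusteringParams:
    """Parameters of the growth phase.

    ``d`` is the local clustering threshold: the maximum number of
    differences per capture link (default 1, the finest partition of
    amplicon-space).  ``threads`` is accepted for interface compatibility;
    results are independent of it by contract (the reference implementation
    is sequential).
    """

    d: int = 1
    scoring: ScoringSystem = field(default_factory=ScoringSystem)
    break_otus: bool = True
    threads: int = 1

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("local clustering threshold d must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


class OtuStats(NamedTuple):
    unique_count: int
    total_abundance: int
    seed_id: str
    seed_abundance: int
    singleton_count: int
    max_generation: int
    max_radius: int


@dataclass
class Otu:
    """One cluster: members, capture tree, generations, statistics.

    ``capture_edges`` form a tree rooted at the seed; every edge carries the
    exact difference count (<= d) between parent and child.  ``members`` are
    ordered seed first, then breadth-first by generation in capture order.
    ``seed_distance`` maps each member to its exact difference count to the
    seed (from the seed comparison pass, or re-aligned after a break).
    """

    seed: Amplicon
    members: list[Amplicon]
    generation_of: dict[str, int]
    capture_edges: list[tuple[str, str, int]]
    seed_distance: dict[str, int]
    stats: OtuStats = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.stats is None:
            self.stats = compute_stats(self)

    @property
    def member_ids(self) -> list[str]:
        return [m.identifier for m in self.members]

    @property
    def total_abundance(self) -> int:
        return sum(m.abundance for m in self.members)


@dataclass(frozen=True)
class ClusteringResult:
    """An ordered list of OTUs forming a partition of the input pool."""

    otus: tuple[Otu, ...]
    params: ClusteringParams

    @property
    def partition(self) -> dict[str, int]:
        """Mapping amplicon identifier -> OTU index."""
        mapping: dict[str, int] = {}
        for index, otu in enumerate(self.otus):
            for member in otu.members:
                mapping[member.identifier] = index
        return mapping

    def membership(self) -> set[frozenset[str]]:
        """The partition as a set of member-identifier sets."""
        return {frozenset(otu.member_ids) for otu in self.otus}


def compute_stats(otu: Otu) -> OtuStats:
    """Evaluate the seven per-OTU statistics fields.

    max_radius is the maximum over members of the cumulated capture-edge
    differences along the path from the seed.
    """
    radius: dict[str, int] = {otu.seed.identifier: 0}
    for parent, child, differences in otu.capture_edges:
        radius[child] = radius[parent] + differences
    return OtuStats(
        unique_count=len(otu.members),
        total_abundance=sum(m.abundance for m in otu.members),
        seed_id=otu.seed.identifier,
        seed_abundance=otu.seed.abundance,
        singleton_count=sum(1 for m in otu.members if m.abundance == 1),
        max_generation=max(otu.generation_of.values(), default=0),
        max_radius=max(radius.values(), default=0),
    )


def generation_filter(
    g: int,
    d: int,
    seed_distance: Optional[int] = None,
    profile_distance_to_seed: Optional[int] = None,
    k: int = K_DEFAULT,
) -> bool:
    """Can a pool amplicon possibly be captured by a generation-g subseed?

    A candidate within d of a generation-g subseed is within (g+1)*d *edits*
    of the seed, so candidates certified to be further away can be skipped.
    The counted difference (from a penalty-optimal alignment) is a quick
    accept when it is within the bound, but it only upper-bounds nothing --
    it can exceed the true edit distance, so exceeding the bound is not by
    itself proof of ineligibility.  Exclusion is therefore certified through
    the k-mer parity lower bound on the edit distance when a profile
    distance is supplied; with only a counted distance available the bound
    is applied to it directly (the classical filter).  Either way a
    candidate truly within d of the subseed is never excluded when the
    profile distance is provided.
    """
    if g < 1:
        raise ValueError("generation must be >= 1")
    bound = (g + 1) * d
    if seed_distance is not None and seed_distance <= bound:
        return True
    if profile_distance_to_seed is not None:
        return difference_lower_bound(profile_distance_to_seed, k) <= bound
    return seed_distance is None


class _Workspace:
    """Precomputed per-amplicon data shared across OTU growths."""

    def __init__(
        self,
        amplicons: Sequence[Amplicon],
        penalties: PenaltySystem,
        k: int = K_DEFAULT,
    ) -> None:
        self.amplicons = list(amplicons)
        self.penalties = penalties
        self.k = k
        self.codes = [encode_sequence(a.sequence) for a in self.amplicons]
        self.lengths = np.array([c.size for c in self.codes], dtype=np.int64)
        if self.amplicons:
            self.bits = np.stack(
                [build_profile(a.sequence, k).bits for a in self.amplicons]
            )
        else:
            self.bits = np.zeros((0, 4**k // 8), dtype=np.uint8)

    def differences(self, i: int, j: int) -> int:
        ops = _gotoh_ops(self.codes[i], self.codes[j], *self.penalties.doubled)
        return int(np.count_nonzero(ops))

    def candidate_mask(self, i: int, candidates: np.ndarray, d: int) -> np.ndarray:
        """Apply the length and 2dk parity filters against amplicon i."""
        ok = np.abs(self.lengths[candidates] - self.lengths[i]) <= d
        if ok.any():
            sub = candidates[ok]
            xor = self.bits[sub] ^ self.bits[i]
            parity = np.bitwise_count(xor).sum(axis=1)
            keep = parity <= 2 * d * self.k
            mask = np.zeros(candidates.size, dtype=bool)
            mask[np.flatnonzero(ok)[keep]] = True
            return mask
        return ok


def _grow(
    workspace: _Workspace, seed_index: int, alive: np.ndarray, params: ClusteringParams
) -> Otu:
    """Grow one OTU from a seed, removing captured amplicons from the pool."""
    d = params.d
    amplicons = workspace.amplicons
    seed = amplicons[seed_index]
    remaining = np.flatnonzero(alive)

    # Seed pass: exact differences to every remaining amplicon (generation-1
    # capture and bookkeeping), plus the seed's parity distances, which
    # certify generation-filter exclusions in later passes.
    seed_distance_by_index = {
        int(i): workspace.differences(seed_index, int(i)) for i in remaining
    }
    if remaining.size:
        parity = np.bitwise_count(
            workspace.bits[remaining] ^ workspace.bits[seed_index]
        ).sum(axis=1)
        seed_parity_by_index = {
            int(i): int(p) for i, p in zip(remaining, parity)
        }
    else:
        seed_parity_by_index = {}

    members = [seed]
    generation_of = {seed.identifier: 0}
    capture_edges: list[tuple[str, str, int]] = []
    seed_distance = {seed.identifier: 0}

    current_generation: list[int] = []
    for i in remaining:
        i = int(i)
        if seed_distance_by_index[i] <= d:
            alive[i] = False
            current_generation.append(i)
            child = amplicons[i]
            members.append(child)
            generation_of[child.identifier] = 1
            capture_edges.append(
                (seed.identifier, child.identifier, seed_distance_by_index[i])
            )
            seed_distance[child.identifier] = seed_distance_by_index[i]

    g = 1
    while current_generation:
        next_generation: list[int] = []
        for subseed_index in current_generation:
            pool_indices = np.flatnonzero(alive)
            if pool_indices.size == 0:
                break
            eligible = np.array(
                [
                    i
                    for i in pool_indices
                    if generation_filter(
                        g,
                        d,
                        seed_distance=seed_distance_by_index[int(i)],
                        profile_distance_to_seed=seed_parity_by_index[int(i)],
                        k=workspace.k,
                    )
                ],
                dtype=np.int64,
            )
            if eligible.size == 0:
                continue
            mask = workspace.candidate_mask(subseed_index, eligible, d)
            for i in eligible[mask]:
                i = int(i)
                differences = workspace.differences(subseed_index, i)
                if differences <= d:
                    alive[i] = False
                    next_generation.append(i)
                    child = amplicons[i]
                    members.append(child)
                    generation_of[child.identifier] = g + 1
                    capture_edges.append(
                        (amplicons[subseed_index].identifier, child.identifier,
                         differences)
                    )
                    seed_distance[child.identifier] = seed_distance_by_index[i]
        current_generation = next_generation
        g += 1

    return Otu(
        seed=seed,
        members=members,
        generation_of=generation_of,
        capture_edges=capture_edges,
        seed_distance=seed_distance,
    )


def grow_otu(
    seed: Amplicon,
    pool: Sequence[Amplicon],
    params: Optional[ClusteringParams] = None,
) -> tuple[Otu, list[Amplicon]]:
    """Grow a single OTU from ``seed`` against ``pool`` (seed not in pool).

    Returns the OTU and the amplicons left uncaptured, in pool order.
    """
    if params is None:
        params = ClusteringParams()
    amplicons = [seed, *pool]
    workspace = _Workspace(amplicons, transform_scoring(params.scoring))
    alive = np.ones(len(amplicons), dtype=bool)
    alive[0] = False
    otu = _grow(workspace, 0, alive, params)
    leftover = [amplicons[int(i)] for i in np.flatnonzero(alive)]
    return otu, leftover


def swarm_cluster(
    pool: AmpliconPool | Iterable[Amplicon],
    params: Optional[ClusteringParams] = None,
) -> ClusteringResult:
    """Partition a dereplicated amplicon pool into OTUs.

    Seeds are taken in pool order (most-abundant-first after dereplication);
    OTUs are emitted in seed-selection order.  The partition, as a set of
    member sets, is invariant under any permutation of the input.
    """
    if params is None:
        params = ClusteringParams()
    amplicons = list(pool)
    workspace = _Workspace(amplicons, transform_scoring(params.scoring))
    alive = np.ones(len(amplicons), dtype=bool)
    otus: list[Otu] = []
    for seed_index in range(len(amplicons)):
        if not alive[seed_index]:
            continue
        alive[seed_index] = False
        otus.append(_grow(workspace, seed_index, alive, params))
    return ClusteringResult(otus=tuple(otus), params=params)
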