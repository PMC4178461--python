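"""Growth phase: single-linkage semantics, order independence, invariants."""

import numpy as np
import pytest

from ampliswarm.bench import CommunitySpec, generate_community
from ampliswarm.cluster import (
    ClusteringParams,
    ClusteringResult,
    compute_stats,
    generation_filter,
    grow_otu,
    swarm_cluster,
)
from ampliswarm.io import Amplicon, AmpliconPool
from conftest import make_pool, random_dna
from oracles import pairwise_difference_matrix, single_linkage_membership


def mutated(seq: str, n_subs: int) -> str:
    out = list(seq)
    for p in range(n_subs):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
    return "".join(out)


BASE = "ACGTACGTACGTACGTACGT"


def test_empty_pool_gives_empty_result():
    result = swarm_cluster(AmpliconPool(()))
    assert result.otus == ()
    assert result.partition == {}


def test_chain_and_outlier_partition():
    """A 1-edit chain forms one OTU; a distant amplicon stays apart."""
    pool = make_pool(
        [
            ("A", BASE, 10),
            ("B", mutated(BASE, 1), 5),
            ("C", mutated(BASE, 2), 2),
            ("D", mutated(BASE, 8), 7),
        ]
    )
    result = swarm_cluster(pool, ClusteringParams(d=1))
    assert result.membership() == {frozenset("ABC"), frozenset("D")}


def test_grow_singleton():
    seed = Amplicon("s", BASE, 9)
    far = Amplicon("f", mutated(BASE, 9), 1)
    otu, leftover = grow_otu(seed, [far], ClusteringParams(d=1))
    assert otu.member_ids == ["s"]
    assert [a.identifier for a in leftover] == ["f"]
    assert otu.stats.max_generation == 0
    assert otu.stats.max_radius == 0


def test_grow_single_capture_at_distance_d():
    seed = Amplicon("s", BASE, 9)
    near = Amplicon("n", mutated(BASE, 2), 1)
    otu, leftover = grow_otu(seed, [near], ClusteringParams(d=2))
    assert otu.member_ids == ["s", "n"]
    assert leftover == []
    assert otu.stats.max_generation == 1
    assert otu.stats.max_radius == 2
    assert otu.capture_edges == [("s", "n", 2)]


def test_generation_chain_and_radius():
    seed = Amplicon("s", BASE, 9)
    x1 = Amplicon("x1", mutated(BASE, 1), 2)
    x2 = Amplicon("x2", mutated(BASE, 2), 1)
    otu, _ = grow_otu(seed, [x1, x2], ClusteringParams(d=1))
    assert otu.generation_of == {"s": 0, "x1": 1, "x2": 2}
    assert otu.stats.max_generation == 2
    assert otu.stats.max_radius == 2
    assert otu.seed_distance == {"s": 0, "x1": 1, "x2": 2}
    stats = compute_stats(otu)
    assert stats == (3, 12, "s", 9, 1, 2, 2)


class TestGenerationFilter:
    def test_exact_distance_boundary(self):
        # A generation-1 subseed may reach candidates up to 2d from the seed.
        assert generation_filter(1, 2, seed_distance=4) is True
        assert generation_filter(1, 2, seed_distance=5) is False

    def test_profile_lower_bound_is_conservative(self):
        assert generation_filter(1, 1, profile_distance_to_seed=20, k=5) is True
        assert generation_filter(1, 1, profile_distance_to_seed=21, k=5) is False

    def test_unknown_distance_is_eligible(self):
        assert generation_filter(3, 1) is True

    def test_counted_distance_above_bound_needs_a_certificate(self):
        # Counted differences can exceed the true edit distance, so a large
        # counted value alone must not exclude when the parity bound allows.
        assert (
            generation_filter(1, 1, seed_distance=3, profile_distance_to_seed=8)
            is True
        )
        assert (
            generation_filter(1, 1, seed_distance=3, profile_distance_to_seed=40)
            is False
        )


def _random_structured_pool(rng: np.random.Generator, n_max: int = 80):
    spec = CommunitySpec(
        n_species=int(rng.integers(2, 6)),
        abundance_model="even",
        even_abundance=int(rng.integers(10, 30)),
        template_length=int(rng.integers(60, 100)),
        min_interspecies_differences=int(rng.integers(7, 12)),
        error_lambda=0.8,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    pool, _ = generate_community(spec)
    return AmpliconPool(pool.amplicons[:n_max])


def test_partition_equals_single_linkage_components(default_penalties):
    """The grown partition is exactly the connected components of the
    <=d-difference graph, for several random pools and d values."""
    rng = np.random.default_rng(31)
    for _ in range(4):
        pool = _random_structured_pool(rng)
        ids = [a.identifier for a in pool]
        matrix = pairwise_difference_matrix(
            [a.sequence for a in pool], default_penalties
        )
        for d in (1, 2):
            result = swarm_cluster(pool, ClusteringParams(d=d))
            assert result.membership() == single_linkage_membership(ids, matrix, d)


def test_input_order_invariance():
    rng = np.random.default_rng(41)
    pool = _random_structured_pool(rng, n_max=50)
    reference = swarm_cluster(pool, ClusteringParams(d=1)).membership()
    for _ in range(20):
        order = rng.permutation(len(pool))
        shuffled = AmpliconPool(tuple(pool[int(i)] for i in order))
        assert swarm_cluster(shuffled, ClusteringParams(d=1)).membership() == reference


def test_thread_count_does_not_change_results():
    rng = np.random.default_rng(43)
    pool = _random_structured_pool(rng, n_max=40)
    results = [
        swarm_cluster(pool, ClusteringParams(d=1, threads=t)) for t in (1, 2, 8)
    ]
    assert all(r.membership() == results[0].membership() for r in results)
    assert all(
        [o.stats for o in r.otus] == [o.stats for o in results[0].otus]
        for r in results
    )


def check_separation_and_contiguity(
    result: ClusteringResult, matrix, ids, d: int
) -> None:
    index = {identifier: i for i, identifier in enumerate(ids)}
    partition = result.partition
    # Separation: any two amplicons in different OTUs are > d apart.
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if partition[ids[i]] != partition[ids[j]]:
                assert matrix[i][j] >= d + 1
    for otu in result.otus:
        # Contiguity: the capture edges form a spanning tree with edges <= d.
        reached = {otu.seed.identifier}
        for parent, child, differences in otu.capture_edges:
            assert differences <= d
            assert matrix[index[parent]][index[child]] == differences
            assert parent in reached
            reached.add(child)
        assert reached == set(otu.member_ids)
        # Generations increase along edges; radius bound.
        for parent, child, _ in otu.capture_edges:
            assert otu.generation_of[child] == otu.generation_of[parent] + 1
        assert otu.stats.max_radius <= max(otu.stats.max_generation, 0) * d


def test_separation_and_contiguity_invariants(default_penalties):
    rng = np.random.default_rng(47)
    for _ in range(3):
        pool = _random_structured_pool(rng, n_max=60)
        ids = [a.identifier for a in pool]
        matrix = pairwise_difference_matrix(
            [a.sequence for a in pool], default_penalties
        )
        for d in (1, 2):
            result = swarm_cluster(pool, ClusteringParams(d=d))
            check_separation_and_contiguity(result, matrix, ids, d)


def test_abundance_conservation(small_community):
    pool, _ = small_community
    result = swarm_cluster(pool)
    assert sum(o.stats.total_abundance for o in result.otus) == pool.total_abundance


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ClusteringParams(d=0)
    with pytest.raises(ValueError):
        ClusteringParams(threads=0)
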