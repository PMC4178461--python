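"""Breaking phase: peak detection, valley verdicts, chain cutting."""

import pytest

from ampliswarm.bench import generate_chained_community, precision
from ampliswarm.breaker import (
    BreakerParams,
    break_otu,
    evaluate_path,
    find_peaks,
    refine,
)
from ampliswarm.cluster import ClusteringParams, swarm_cluster
from conftest import make_pool


def chain_otu(abundances, d=1):
    """A linear capture chain of amplicons with the given abundances."""
    base = "ACGTACGTACGTACGTACGTACGTACGT"
    records = []
    seq = base
    for i, abundance in enumerate(abundances):
        records.append((f"m{i}", seq, abundance))
        seq = seq[: 2 * i] + "ACGT"[("ACGT".index(seq[2 * i]) + 1) % 4] + seq[2 * i + 1 :]
    pool = make_pool(records)
    result = swarm_cluster(pool, ClusteringParams(d=d))
    assert len(result.otus) == 1
    return result.otus[0]


class TestFindPeaks:
    def test_no_peaks_below_threshold(self):
        otu = chain_otu([99, 2, 98])
        assert find_peaks(otu) == []

    def test_peaks_sorted_by_abundance(self):
        otu = chain_otu([500, 2, 1000, 1])
        assert [m.abundance for m in find_peaks(otu)] == [1000, 500]

    def test_boundary_abundance_is_a_peak(self):
        otu = chain_otu([100, 1, 1000])
        assert {m.abundance for m in find_peaks(otu)} == {100, 1000}


class TestEvaluatePath:
    def test_deep_valley_is_breakable(self):
        otu = chain_otu([1000, 2, 500])
        peaks = find_peaks(otu)
        verdict = evaluate_path(otu, peaks[0], peaks[1])
        assert verdict.valley_min.abundance == 2
        assert verdict.ratio == pytest.approx(250.0)
        assert verdict.breakable

    def test_shallow_valley_is_not_breakable(self):
        otu = chain_otu([200, 100, 150], d=1)
        params = BreakerParams(peak_min_abundance=100)
        peaks = find_peaks(otu, params)
        assert [p.abundance for p in peaks] == [200, 150, 100]
        verdict = evaluate_path(otu, peaks[0], peaks[1], params)
        assert verdict.ratio == pytest.approx(1.5)
        assert not verdict.breakable

    def test_adjacent_peaks_have_no_valley(self):
        otu = chain_otu([1000, 500])
        peaks = find_peaks(otu)
        verdict = evaluate_path(otu, peaks[0], peaks[1])
        assert verdict.valley_min is None
        assert not verdict.breakable

    def test_plateau_does_not_count_as_valley(self):
        # Interior abundance equals the secondary peak: no down-then-up shape.
        otu = chain_otu([1000, 500, 500])
        peaks = find_peaks(otu)
        verdict = evaluate_path(otu, peaks[0], peaks[2])
        assert not verdict.breakable

    def test_primary_must_dominate(self):
        otu = chain_otu([1000, 2, 500])
        peaks = find_peaks(otu)
        with pytest.raises(ValueError):
            evaluate_path(otu, peaks[1], peaks[0])


class TestBreakOtu:
    def test_single_peak_unchanged(self):
        otu = chain_otu([1000, 2, 3])
        assert break_otu(otu) == [otu]

    def test_low_abundance_otu_not_searched(self):
        otu = chain_otu([99, 1, 98])
        assert break_otu(otu) == [otu]

    def test_two_star_chain_splits_into_two_otus(self, chained_pool):
        pool, _ = chained_pool
        result = swarm_cluster(pool, ClusteringParams(d=1))
        assert len(result.otus) == 1
        pieces = break_otu(result.otus[0])
        assert len(pieces) == 2
        seeds = sorted(p.seed.abundance for p in pieces)
        assert seeds == [500, 1000]
        # Membership and abundance are conserved across the cut.
        assert sorted(m for p in pieces for m in p.member_ids) == sorted(
            result.otus[0].member_ids
        )
        assert sum(p.total_abundance for p in pieces) == result.otus[0].total_abundance
        # The bridge stays attached to the side it still connects to.
        bridge_home = {p.seed.abundance: p.member_ids for p in pieces}
        assert "bridge1" in bridge_home[500]

    def test_rebuilt_otus_have_consistent_structure(self, chained_pool):
        pool, _ = chained_pool
        result = swarm_cluster(pool, ClusteringParams(d=1))
        for piece in break_otu(result.otus[0]):
            assert piece.members[0] is piece.seed
            assert piece.generation_of[piece.seed.identifier] == 0
            reached = {piece.seed.identifier}
            for parent, child, differences in piece.capture_edges:
                assert parent in reached
                assert differences <= 1
                reached.add(child)
                assert (
                    piece.generation_of[child]
                    == piece.generation_of[parent] + 1
                )
            assert reached == set(piece.member_ids)
            assert piece.seed_distance[piece.seed.identifier] == 0
            assert piece.stats.unique_count == len(piece.members)


class TestRefine:
    def test_refinement_splits_only(self, chained_pool):
        pool, _ = chained_pool
        before = swarm_cluster(pool, ClusteringParams(d=1))
        after = refine(before)
        assert len(after.otus) > len(before.otus)
        before_sets = before.membership()
        for otu in after.otus:
            members = set(otu.member_ids)
            assert sum(members <= s for s in before_sets) == 1
        assert sum(o.stats.total_abundance for o in after.otus) == sum(
            o.stats.total_abundance for o in before.otus
        )

    def test_shallow_valley_left_intact(self, shallow_valley_pool):
        pool, _ = shallow_valley_pool
        before = swarm_cluster(pool, ClusteringParams(d=1))
        after = refine(before)
        assert after.membership() == before.membership()

    def test_idempotent(self, chained_pool):
        pool, _ = chained_pool
        once = refine(swarm_cluster(pool, ClusteringParams(d=1)))
        twice = refine(once)
        assert twice.membership() == once.membership()
        assert [o.member_ids for o in twice.otus] == [o.member_ids for o in once.otus]

    def test_precision_non_decreasing(self, chained_pool):
        pool, truth = chained_pool
        before = swarm_cluster(pool, ClusteringParams(d=1))
        after = refine(before)
        assert precision(after.partition, truth.assignment) >= precision(
            before.partition, truth.assignment
        )

    def test_raising_valley_ratio_cannot_add_breaks(self, chained_pool):
        pool, _ = chained_pool
        before = swarm_cluster(pool, ClusteringParams(d=1))
        counts = [
            len(refine(before, BreakerParams(valley_ratio=r)).otus)
            for r in (10.0, 50.0, 300.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_raising_peak_threshold_cannot_add_breaks(self, chained_pool):
        pool, _ = chained_pool
        before = swarm_cluster(pool, ClusteringParams(d=1))
        counts = [
            len(refine(before, BreakerParams(peak_min_abundance=p)).otus)
            for p in (100, 501, 1001)
        ]
        assert counts == sorted(counts, reverse=True)


def test_invalid_breaker_params_rejected():
    with pytest.raises(ValueError):
        BreakerParams(peak_min_abundance=0)
    with pytest.raises(ValueError):
        BreakerParams(valley_ratio=1.0)
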