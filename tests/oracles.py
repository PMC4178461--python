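"""Independent reference implementations used as test oracles.

Everything here recomputes results by brute force or by an independent
formulation (full enumeration, plain DP, pairwise graph components) and is
deliberately kept separate from the package's own code paths.
"""

from __future__ import annotations

from math import inf

import networkx as nx

from ampliswarm.align import PenaltySystem, ScoringSystem, count_differences

# Alignments are represented as tuples over {'A', 'D', 'I'}: 'A' consumes one
# residue of each sequence, 'D' one of the first only, 'I' one of the second.


def enumerate_alignments(m: int, n: int):
    """Every global alignment of sequences of lengths m and n."""
    if m == 0 and n == 0:
        yield ()
        return
    if m > 0 and n > 0:
        for rest in enumerate_alignments(m - 1, n - 1):
            yield ("A",) + rest
    if m > 0:
        for rest in enumerate_alignments(m - 1, n):
            yield ("D",) + rest
    if n > 0:
        for rest in enumerate_alignments(m, n - 1):
            yield ("I",) + rest


def similarity_score(a: str, b: str, ops, scoring: ScoringSystem) -> int:
    """Affine similarity score of one alignment (gap of length L scores
    gap_open + L * gap_extend)."""
    i = j = 0
    score = 0
    previous = None
    for op in ops:
        if op == "A":
            score += scoring.match if a[i] == b[j] else scoring.mismatch
            i += 1
            j += 1
        else:
            if op != previous:
                score += scoring.gap_open
            score += scoring.gap_extend
            if op == "D":
                i += 1
            else:
                j += 1
        previous = op
    return score


def doubled_penalty(a: str, b: str, ops, doubled: tuple[int, int, int]) -> int:
    """Doubled-scale penalty of one alignment."""
    mismatch2, open2, extend2 = doubled
    i = j = 0
    cost = 0
    previous = None
    for op in ops:
        if op == "A":
            if a[i] != b[j]:
                cost += mismatch2
            i += 1
            j += 1
        else:
            if op != previous:
                cost += open2
            cost += extend2
            if op == "D":
                i += 1
            else:
                j += 1
        previous = op
    return cost


def brute_force_optimal_sets(
    a: str, b: str, scoring: ScoringSystem, doubled: tuple[int, int, int]
):
    """(similarity-optimal set, penalty-optimal set) by full enumeration."""
    alignments = list(enumerate_alignments(len(a), len(b)))
    sim = [similarity_score(a, b, ops, scoring) for ops in alignments]
    pen = [doubled_penalty(a, b, ops, doubled) for ops in alignments]
    best_sim = max(sim)
    best_pen = min(pen)
    return (
        {ops for ops, s in zip(alignments, sim) if s == best_sim},
        {ops for ops, p in zip(alignments, pen) if p == best_pen},
    )


def dp_optimal_set(a: str, b: str, sub_cost, open_cost, extend_cost):
    """All cost-minimizing global alignments under an affine gap model.

    ``sub_cost(x, y)`` is the cost of aligning residues x and y; a gap of
    length L costs open_cost + L * extend_cost.  Plain three-state DP with
    exhaustive traceback of every co-optimal path.
    """
    m, n = len(a), len(b)
    gap1 = open_cost + extend_cost
    H = [[inf] * (n + 1) for _ in range(m + 1)]
    E = [[inf] * (n + 1) for _ in range(m + 1)]
    F = [[inf] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for i in range(1, m + 1):
        E[i][0] = gap1 + extend_cost * (i - 1)
        H[i][0] = E[i][0]
    for j in range(1, n + 1):
        F[0][j] = gap1 + extend_cost * (j - 1)
        H[0][j] = F[0][j]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = min(H[i - 1][j] + gap1, E[i - 1][j] + extend_cost)
            F[i][j] = min(H[i][j - 1] + gap1, F[i][j - 1] + extend_cost)
            H[i][j] = min(
                H[i - 1][j - 1] + sub_cost(a[i - 1], b[j - 1]), E[i][j], F[i][j]
            )

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def collect(i: int, j: int, state: str) -> frozenset:
        if i == 0 and j == 0 and state == "H":
            return frozenset({()})
        paths = set()
        if state == "H":
            if (
                i > 0
                and j > 0
                and H[i][j] == H[i - 1][j - 1] + sub_cost(a[i - 1], b[j - 1])
            ):
                paths.update(
                    p + ("A",) for p in collect(i - 1, j - 1, "H")
                )
            if i > 0 and H[i][j] == E[i][j]:
                paths.update(collect(i, j, "E"))
            if j > 0 and H[i][j] == F[i][j]:
                paths.update(collect(i, j, "F"))
        elif state == "E":
            if E[i][j] == H[i - 1][j] + gap1:
                paths.update(p + ("D",) for p in collect(i - 1, j, "H"))
            if i > 1 and E[i][j] == E[i - 1][j] + extend_cost:
                paths.update(p + ("D",) for p in collect(i - 1, j, "E"))
        else:
            if F[i][j] == H[i][j - 1] + gap1:
                paths.update(p + ("I",) for p in collect(i, j - 1, "H"))
            if j > 1 and F[i][j] == F[i][j - 1] + extend_cost:
                paths.update(p + ("I",) for p in collect(i, j - 1, "F"))
        return frozenset(paths)

    return set(collect(m, n, "H"))


def similarity_optimal_set(a: str, b: str, scoring: ScoringSystem):
    """Similarity-maximizing alignments, via cost minimization of the negation."""
    def sub_cost(x, y):
        return -(scoring.match if x == y else scoring.mismatch)

    return dp_optimal_set(a, b, sub_cost, -scoring.gap_open, -scoring.gap_extend)


def penalty_optimal_set(a: str, b: str, doubled: tuple[int, int, int]):
    mismatch2, open2, extend2 = doubled

    def sub_cost(x, y):
        return 0 if x == y else mismatch2

    return dp_optimal_set(a, b, sub_cost, open2, extend2)


def optimal_similarity_score(a: str, b: str, scoring: ScoringSystem) -> int:
    """Maximum affine similarity score (plain DP, no traceback)."""
    m, n = len(a), len(b)
    gap1 = scoring.gap_open + scoring.gap_extend
    H = [[-inf] * (n + 1) for _ in range(m + 1)]
    E = [[-inf] * (n + 1) for _ in range(m + 1)]
    F = [[-inf] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for i in range(1, m + 1):
        E[i][0] = gap1 + scoring.gap_extend * (i - 1)
        H[i][0] = E[i][0]
    for j in range(1, n + 1):
        F[0][j] = gap1 + scoring.gap_extend * (j - 1)
        H[0][j] = F[0][j]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] + gap1, E[i - 1][j] + scoring.gap_extend)
            F[i][j] = max(H[i][j - 1] + gap1, F[i][j - 1] + scoring.gap_extend)
            sub = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            H[i][j] = max(H[i - 1][j - 1] + sub, E[i][j], F[i][j])
    return H[m][n]


def cigar_to_ops(cigar: str) -> tuple:
    """Package CIGAR (M/X/D/I runs) to the oracle op representation."""
    import re

    ops: list[str] = []
    for match in re.finditer(r"(\d+)([MXDI])", cigar):
        run, op = int(match.group(1)), match.group(2)
        ops.extend(["A" if op in "MX" else op] * run)
    return tuple(ops)


def pairwise_difference_matrix(sequences, penalties: PenaltySystem):
    """All-pairs difference counts (upper triangle mirrored)."""
    n = len(sequences)
    matrix = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = count_differences(sequences[i], sequences[j], penalties)
            matrix[i][j] = matrix[j][i] = d
    return matrix


def single_linkage_membership(identifiers, matrix, d: int):
    """Connected components of the <=d-difference graph, as id sets."""
    graph = nx.Graph()
    graph.add_nodes_from(identifiers)
    n = len(identifiers)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i][j] <= d:
                graph.add_edge(identifiers[i], identifiers[j])
    return {frozenset(c) for c in nx.connected_components(graph)}
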