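"""Synthetic mock communities with known ground truth, and clustering metrics.

The generator emulates a dereplicated marker-gene survey: each species
contributes one random template sequence, templates are kept at least
``min_interspecies_differences`` edits apart (rejection sampling), species
copy numbers follow either an even or a log-normal abundance model, and each
copy is independently mutated with a capped-Poisson number of edits
(substitution / insertion / deletion).  Because per-copy edits are capped at
``max_edits_per_copy`` and templates are far apart, species clouds are
separated by construction: for every local threshold d in the designed
window [max_edits_per_copy, min_interspecies_differences -
2*max_edits_per_copy - 1] single-linkage growth recovers exactly the
species partition.

Clustering quality is scored against the ground truth with pair-counting
metrics over unique amplicons: recall (same-species pairs co-clustered),
precision (co-clustered pairs that share a species), and the Hubert-Arabie
adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Hashable, Mapping, Optional

import numpy as np

from .io import Amplicon, AmpliconPool, dereplicate

__all__ = [
    "CommunitySpec",
    "GroundTruth",
    "generate_community",
    "generate_chained_community",
    "designed_d_window",
    "recall",
    "precision",
    "adjusted_rand_index",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic amplicon community.

    ``abundance_model`` is ``"even"`` (``even_abundance`` copies per
    species) or ``"lognormal"`` (copies ~ round(LogNormal(mu, sigma)),
    floored at 1: a few abundant species, many rare ones).
    """

    n_species: int = 20
    abundance_model: str = "lognormal"
    even_abundance: int = 100
    lognormal_mu: float = 4.0
    lognormal_sigma: float = 1.0
    template_length: int = 150
    min_interspecies_differences: int = 13
    error_lambda: float = 0.3
    error_weights: tuple[float, float, float] = (0.8, 0.1, 0.1)
    max_edits_per_copy: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.abundance_model not in ("even", "lognormal"):
            raise ValueError("abundance_model must be 'even' or 'lognormal'")
        if self.template_length < 1:
            raise ValueError("template_length must be >= 1")
        if abs(sum(self.error_weights) - 1.0) > 1e-9:
            raise ValueError("error_weights must sum to 1")
        if self.min_interspecies_differences < 2 * self.max_edits_per_copy + 1:
            raise ValueError(
                "min_interspecies_differences must be >= "
                "2 * max_edits_per_copy + 1 so species clouds cannot touch"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Total mapping from amplicon identifier to species label."""

    assignment: Mapping[str, str]


def designed_d_window(spec: CommunitySpec) -> tuple[int, int]:
    """The [d_lo, d_hi] range over which species recovery is guaranteed.

    d >= max_edits_per_copy links every variant directly to its template;
    d <= min_interspecies_differences - 2*max_edits_per_copy - 1 keeps the
    inter-cloud gap wider than d.
    """
    return (
        spec.max_edits_per_copy,
        spec.min_interspecies_differences - 2 * spec.max_edits_per_copy - 1,
    )


def _hamming_bounded(a: str, b: str, bound: int) -> bool:
    """True if the per-position mismatch count of equal-length strings < bound."""
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches >= bound:
                return False
    return True


def _sample_templates(spec: CommunitySpec, rng: np.random.Generator) -> list[str]:
    # Equal-length templates: Hamming distance bounds alignment differences
    # from above, so enforcing the floor on Hamming distance is sufficient.
    templates: list[str] = []
    attempts = 0
    max_attempts = 200 * spec.n_species
    while len(templates) < spec.n_species:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place templates at the requested minimum distance; "
                "the community specification is infeasible"
            )
        candidate = "".join(
            rng.choice(list(_BASES), size=spec.template_length)
        )
        if all(
            not _hamming_bounded(candidate, t, spec.min_interspecies_differences)
            for t in templates
        ):
            templates.append(candidate)
    return templates


def _mutate(sequence: str, n_edits: int, weights, rng: np.random.Generator) -> str:
    """Apply n_edits edits at distinct, right-to-left positions."""
    if n_edits == 0:
        return sequence
    seq = list(sequence)
    positions = sorted(
        rng.choice(len(seq), size=min(n_edits, len(seq)), replace=False),
        reverse=True,
    )
    for position in positions:
        kind = rng.choice(3, p=list(weights))
        if kind == 0:  # substitution
            current = seq[position]
            seq[position] = rng.choice([b for b in _BASES if b != current])
        elif kind == 1:  # insertion
            seq.insert(position, rng.choice(list(_BASES)))
        else:  # deletion
            if len(seq) > 1:
                del seq[position]
    return "".join(seq)


def _species_abundance(spec: CommunitySpec, rng: np.random.Generator) -> int:
    if spec.abundance_model == "even":
        return spec.even_abundance
    return max(1, int(round(rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma))))


def generate_community(spec: CommunitySpec) -> tuple[AmpliconPool, GroundTruth]:
    """Generate a dereplicated pool plus ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(spec.rng_seed)
    templates = _sample_templates(spec, rng)

    amplicons: list[Amplicon] = []
    assignment: dict[str, str] = {}
    for species_index, template in enumerate(templates):
        label = f"species{species_index:03d}"
        copies = _species_abundance(spec, rng)
        # Copies are dereplicated within the species: identical mutated
        # sequences merge, and unmutated copies accumulate on the template.
        counts: dict[str, int] = {}
        n_edits = np.minimum(
            rng.poisson(spec.error_lambda, size=copies), spec.max_edits_per_copy
        )
        counts[template] = int(np.count_nonzero(n_edits == 0))
        for k in n_edits[n_edits > 0]:
            variant = _mutate(template, int(k), spec.error_weights, rng)
            counts[variant] = counts.get(variant, 0) + 1
        if counts[template] == 0:
            del counts[template]
        for variant_index, (sequence, abundance) in enumerate(counts.items()):
            identifier = f"sp{species_index:03d}v{variant_index:04d}"
            amplicons.append(
                Amplicon(identifier=identifier, sequence=sequence,
                         abundance=abundance)
            )
            assignment[identifier] = label

    pool = dereplicate(AmpliconPool(tuple(amplicons)))
    # Cross-species dereplication cannot occur by construction (clouds are
    # separated), so every input identifier survives.
    return pool, GroundTruth(assignment=assignment)


def generate_chained_community(
    spec: Optional[CommunitySpec] = None,
    bridge_abundance: int = 2,
    n_bridge: int = 5,
    peak_abundances: tuple[int, int] = (1000, 500),
    n_satellites: int = 4,
) -> tuple[AmpliconPool, GroundTruth]:
    """Two abundant species clouds linked by a low-abundance amplicon chain.

    The two peaks are ``n_bridge + 1`` substitutions apart and the bridge
    amplicons interpolate between them one substitution at a time, so growth
    at d=1 merges everything into one OTU while the designed abundance
    valley lets the breaking phase split it again.  With ``n_bridge = 0`` no
    bridge is emitted and the clouds stay separate.
    """
    if spec is None:
        spec = CommunitySpec(n_species=2, rng_seed=0)
    if bridge_abundance < 1:
        raise ValueError("bridge_abundance must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    length = spec.template_length
    template_a = "".join(rng.choice(list(_BASES), size=length))
    # Without a bridge the peaks still need to sit well apart (two isolated
    # clouds); with one, they are exactly n_bridge + 1 substitutions apart.
    n_positions = n_bridge + 1 if n_bridge > 0 else 4
    positions = sorted(
        int(p) for p in rng.choice(length, size=n_positions, replace=False)
    )

    def substituted(base_seq: str, upto: int) -> str:
        seq = list(base_seq)
        for p in positions[:upto]:
            current = seq[p]
            seq[p] = _BASES[(_BASES.index(current) + 1) % 4]
        return "".join(seq)

    template_b = substituted(template_a, n_positions)

    amplicons: list[Amplicon] = []
    assignment: dict[str, str] = {}

    def add(identifier: str, sequence: str, abundance: int, label: str) -> None:
        amplicons.append(Amplicon(identifier, sequence, abundance))
        assignment[identifier] = label

    add("peakA", template_a, peak_abundances[0], "speciesA")
    add("peakB", template_b, peak_abundances[1], "speciesB")
    used = {template_a, template_b}
    used.update(substituted(template_a, step) for step in range(1, n_bridge + 1))
    for side, template, label in (
        ("A", template_a, "speciesA"),
        ("B", template_b, "speciesB"),
    ):
        for s in range(n_satellites):
            variant = _mutate(template, 1, (1.0, 0.0, 0.0), rng)
            while variant in used:
                variant = _mutate(template, 1, (1.0, 0.0, 0.0), rng)
            used.add(variant)
            add(f"sat{side}{s}", variant, int(rng.integers(2, 30)), label)
    for step in range(1, n_bridge + 1):
        label = "speciesA" if step <= (n_bridge + 1) // 2 else "speciesB"
        add(f"bridge{step}", substituted(template_a, step), bridge_abundance, label)

    pool = dereplicate(AmpliconPool(tuple(amplicons)))
    return pool, GroundTruth(assignment=assignment)


def _contingency(
    partition: Mapping[str, Hashable], truth: Mapping[str, Hashable]
) -> np.ndarray:
    if set(partition) != set(truth):
        raise ValueError("partition and ground truth cover different amplicons")
    class_index = {label: i for i, label in enumerate(dict.fromkeys(truth.values()))}
    cluster_index = {
        label: i for i, label in enumerate(dict.fromkeys(partition.values()))
    }
    table = np.zeros((len(class_index), len(cluster_index)), dtype=np.int64)
    for identifier, cluster in partition.items():
        table[class_index[truth[identifier]], cluster_index[cluster]] += 1
    return table


def _pair_sums(table: np.ndarray) -> tuple[int, int, int]:
    together = int(sum(comb(int(n), 2) for n in table.ravel()))
    truth_pairs = int(sum(comb(int(n), 2) for n in table.sum(axis=1)))
    cluster_pairs = int(sum(comb(int(n), 2) for n in table.sum(axis=0)))
    return together, truth_pairs, cluster_pairs


def recall(
    partition: Mapping[str, Hashable], truth: Mapping[str, Hashable]
) -> float:
    """Fraction of same-species amplicon pairs placed in the same OTU.

    1.0 when no same-species pair exists (nothing can be over-split).
    """
    together, truth_pairs, _ = _pair_sums(_contingency(partition, truth))
    return together / truth_pairs if truth_pairs else 1.0


def precision(
    partition: Mapping[str, Hashable], truth: Mapping[str, Hashable]
) -> float:
    """Fraction of co-clustered amplicon pairs that share a species.

    1.0 for an all-singleton partition (no pair is over-grouped).
    """
    together, _, cluster_pairs = _pair_sums(_contingency(partition, truth))
    return together / cluster_pairs if cluster_pairs else 1.0


def adjusted_rand_index(
    partition: Mapping[str, Hashable], truth: Mapping[str, Hashable]
) -> float:
    """Hubert-Arabie adjusted Rand index between a clustering and the truth."""
    table = _contingency(partition, truth)
    together, truth_pairs, cluster_pairs = _pair_sums(table)
    total_pairs = comb(int(table.sum()), 2)
    if total_pairs == 0:
        return 1.0
    expected = truth_pairs * cluster_pairs / total_pairs
    maximum = (truth_pairs + cluster_pairs) / 2
    if maximum == expected:
        return 1.0
    return (together - expected) / (maximum - expected)
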