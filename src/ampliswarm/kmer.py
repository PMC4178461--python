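"""Lossless pre-alignment filtering via k-mer occurrence-parity bit vectors.

Each amplicon is summarized by a 4^k-bit vector whose bit i records whether
the i-th k-mer (lexicographic, A<C<G<T, two bits per base, big-endian over
the k-mer) occurs an odd number of times in the sequence.  A single edit can
change the parity of at most 2k k-mers, so two sequences within d alignment
differences have at most 2*d*k differing bits: pairs further apart in
parity-vector Hamming distance (or differing in length by more than d) can
be discarded without alignment, with false positives possible but never
false negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._encoding import encode_sequence

__all__ = [
    "K_DEFAULT",
    "KmerProfile",
    "build_profile",
    "profile_distance",
    "filter_threshold",
    "length_compatible",
    "difference_lower_bound",
    "candidate_filter",
]

K_DEFAULT = 5  # 4^5 = 1,024-bit vectors


@dataclass(frozen=True)
class KmerProfile:
    """Occurrence-parity vector of all k-mers of one sequence.

    ``bits`` is the 4^k-bit vector packed into uint8 words (big-endian bit
    order); sequences shorter than k have the all-zero vector.
    """

    bits: np.ndarray
    k: int
    sequence_length: int

    @property
    def n_bits(self) -> int:
        return 4**self.k


def build_profile(sequence: str, k: int = K_DEFAULT) -> KmerProfile:
    """Build the k-mer parity profile of a normalized DNA sequence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = encode_sequence(sequence)
    n = codes.size
    size = 4**k
    if n < k:
        parity = np.zeros(size, dtype=np.uint8)
    else:
        idx = np.zeros(n - k + 1, dtype=np.int64)
        for offset in range(k):
            idx = idx * 4 + codes[offset : offset + n - k + 1]
        parity = (np.bincount(idx, minlength=size) & 1).astype(np.uint8)
    bits = np.packbits(parity)
    bits.setflags(write=False)
    return KmerProfile(bits=bits, k=k, sequence_length=n)


def profile_distance(p: KmerProfile, q: KmerProfile) -> int:
    """Hamming distance between two parity vectors (XOR + popcount)."""
    if p.k != q.k:
        raise ValueError(f"profiles built with different k ({p.k} vs {q.k})")
    return int(np.bitwise_count(p.bits ^ q.bits).sum())


def filter_threshold(d: int, k: int) -> int:
    """Maximum parity-vector Hamming distance of two sequences within d edits."""
    if d < 1 or k < 1:
        raise ValueError("d and k must be >= 1")
    return 2 * d * k


def length_compatible(len_a: int, len_b: int, d: int) -> bool:
    """Sequences differing in length by more than d cannot be within d edits."""
    return abs(len_a - len_b) <= d


def difference_lower_bound(distance: int, k: int) -> int:
    """Lower bound on alignment differences implied by a parity distance."""
    return math.ceil(distance / (2 * k))


def candidate_filter(
    reference: KmerProfile, pool: Sequence[KmerProfile], d: int
) -> list[int]:
    """Indices of pool profiles that may be within d differences of reference.

    Applies the length filter and the 2dk parity bound; the returned index
    set is a superset of the truly-within-d set (lossless).
    """
    threshold = filter_threshold(d, reference.k)
    return [
        i
        for i, q in enumerate(pool)
        if length_compatible(reference.sequence_length, q.sequence_length, d)
        and profile_distance(reference, q) <= threshold
    ]
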