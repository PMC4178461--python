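"""Amplicon FASTA input, validation, dereplication, and output writers.

Input is a standard FASTA file of DNA or RNA amplicons with unique
identifiers.  The identifier is the header text up to the first space;
abundance (copy number) annotations are carried either as a terminal ``_N``
suffix (default dialect) or a ``;size=N;`` field.  Sequences are validated
against the {A, C, G, T/U} alphabet, uppercased, and U is mapped to T.

Writers cover the plain OTU list (space-separated member identifiers), the
7-column per-OTU statistics table, a usearch-style .uc table, and the mothur
list format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Optional, TextIO

from Bio import SeqIO

from .align import PenaltySystem, align, transform_scoring

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusteringResult

__all__ = [
    "Amplicon",
    "AmpliconPool",
    "AmpliconFormatError",
    "parse_header",
    "normalize_sequence",
    "read_fasta",
    "dereplicate",
    "write_fasta",
    "write_otu_list",
    "write_stats",
    "write_uclust",
    "write_mothur",
    "compute_alignment_identities",
    "format_label",
]

DIALECTS = ("underscore", "size")

_UNDERSCORE_RE = re.compile(r"^(?P<id>.*)_(?P<ab>\d+)$")
_SIZE_RE = re.compile(r";size=(?P<ab>[^;]*);?")
_TRANSLATE = str.maketrans("acgtuU", "ACGTTT")
_VALID_RE = re.compile(r"^[ACGT]+$")


class AmpliconFormatError(ValueError):
    """Raised for malformed or invalid amplicon input."""


@dataclass(frozen=True)
class Amplicon:
    """One dereplicated amplicon: identifier, normalized sequence, copy number.

    ``label`` preserves the original header token (identifier plus abundance
    annotation) when the record was read from a file and its abundance is
    unchanged; writers fall back to re-synthesizing the annotation.
    """

    identifier: str
    sequence: str
    abundance: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise AmpliconFormatError(
                f"invalid identifier {self.identifier!r}: must be non-empty, "
                "no whitespace"
            )
        if not self.sequence or not _VALID_RE.match(self.sequence):
            raise AmpliconFormatError(
                f"amplicon {self.identifier!r}: sequence must be a non-empty "
                "string over A, C, G, T"
            )
        if self.abundance < 1:
            raise AmpliconFormatError(
                f"amplicon {self.identifier!r}: abundance must be >= 1"
            )


@dataclass(frozen=True)
class AmpliconPool:
    """Ordered collection of amplicons with pairwise-distinct identifiers."""

    amplicons: tuple[Amplicon, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicons", tuple(self.amplicons))
        seen: set[str] = set()
        for amp in self.amplicons:
            if amp.identifier in seen:
                raise AmpliconFormatError(
                    f"duplicate amplicon identifier {amp.identifier!r}"
                )
            seen.add(amp.identifier)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, i: int) -> Amplicon:
        return self.amplicons[i]

    @property
    def total_abundance(self) -> int:
        return sum(a.abundance for a in self.amplicons)


def parse_header(
    header_line: str,
    dialect: str = "underscore",
    default_abundance: Optional[int] = None,
) -> tuple[str, int]:
    """Extract (identifier, abundance) from a FASTA header line.

    The identifier is the text between '>' and the first space, with the
    abundance annotation stripped according to the dialect.  A missing
    annotation yields ``default_abundance``, or an error when none is set.
    """
    if not header_line.startswith(">"):
        raise AmpliconFormatError(f"not a FASTA header: {header_line!r}")
    if dialect not in DIALECTS:
        raise ValueError(f"unknown abundance dialect {dialect!r}")
    token = header_line[1:].split(None, 1)[0] if header_line[1:].strip() else ""
    if not token:
        raise AmpliconFormatError(f"empty identifier in header {header_line!r}")

    if dialect == "underscore":
        m = _UNDERSCORE_RE.match(token)
        if m and m.group("id"):
            abundance = int(m.group("ab"))
            if abundance < 1:
                raise AmpliconFormatError(
                    f"abundance must be a positive integer in header "
                    f"{header_line!r}"
                )
            return m.group("id"), abundance
    else:
        m = _SIZE_RE.search(token)
        if m:
            raw = m.group("ab")
            if not raw.isdigit() or int(raw) < 1:
                raise AmpliconFormatError(
                    f"abundance must be a positive integer in header "
                    f"{header_line!r}"
                )
            identifier = token[: m.start()] + token[m.end() :]
            if not identifier:
                raise AmpliconFormatError(
                    f"empty identifier in header {header_line!r}"
                )
            return identifier, int(raw)

    if default_abundance is None:
        raise AmpliconFormatError(
            f"missing abundance annotation in header {header_line!r} and no "
            "default abundance configured"
        )
    return token, default_abundance


def normalize_sequence(raw: str, context: str = "") -> str:
    """Uppercase, map U to T, and validate the {A,C,G,T} alphabet."""
    if not raw:
        raise AmpliconFormatError(f"empty sequence{context}")
    seq = raw.translate(_TRANSLATE)
    if not _VALID_RE.match(seq):
        bad = next(c for c in seq if c not in "ACGT")
        raise AmpliconFormatError(
            f"invalid symbol {bad!r} in sequence{context}: only A, C, G, T "
            "(or U) are allowed"
        )
    return seq


def read_fasta(
    path,
    dialect: str = "underscore",
    default_abundance: Optional[int] = None,
) -> AmpliconPool:
    """Read a FASTA file into an amplicon pool, in file order."""
    amplicons: list[Amplicon] = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = f">{record.description}"
        identifier, abundance = parse_header(header, dialect, default_abundance)
        sequence = normalize_sequence(
            str(record.seq), context=f" of record {identifier!r}"
        )
        label = record.description.split(None, 1)[0]
        amplicons.append(
            Amplicon(
                identifier=identifier,
                sequence=sequence,
                abundance=abundance,
                label=label,
            )
        )
    return AmpliconPool(tuple(amplicons))


def dereplicate(pool: AmpliconPool) -> AmpliconPool:
    """Merge amplicons with identical sequences; sort by decreasing abundance.

    Merged records sum their abundances and keep the identifier of the most
    abundant constituent (ties: first in input order).  The output is sorted
    by decreasing abundance, ties broken by input order, which is also the
    recommended processing order for clustering.
    """
    groups: dict[str, list[tuple[int, Amplicon]]] = {}
    for position, amp in enumerate(pool):
        groups.setdefault(amp.sequence, []).append((position, amp))

    merged: list[tuple[int, Amplicon]] = []
    for members in groups.values():
        first_position = members[0][0]
        if len(members) == 1:
            merged.append((first_position, members[0][1]))
            continue
        total = sum(a.abundance for _, a in members)
        representative = max(members, key=lambda pa: (pa[1].abundance, -pa[0]))[1]
        merged.append(
            (
                first_position,
                Amplicon(
                    identifier=representative.identifier,
                    sequence=representative.sequence,
                    abundance=total,
                ),
            )
        )
    merged.sort(key=lambda pa: (-pa[1].abundance, pa[0]))
    return AmpliconPool(tuple(a for _, a in merged))


def format_label(amplicon: Amplicon, dialect: str = "underscore") -> str:
    """Identifier with its abundance annotation, as read or re-synthesized."""
    if amplicon.label is not None:
        return amplicon.label
    if dialect == "underscore":
        return f"{amplicon.identifier}_{amplicon.abundance}"
    if dialect == "size":
        return f"{amplicon.identifier};size={amplicon.abundance};"
    raise ValueError(f"unknown abundance dialect {dialect!r}")


def write_fasta(
    amplicons: Iterable[Amplicon], sink: TextIO, dialect: str = "underscore"
) -> None:
    """Write amplicons as FASTA with abundance-annotated headers."""
    for amp in amplicons:
        sink.write(f">{format_label(amp, dialect)}\n{amp.sequence}\n")


def write_otu_list(
    result: "ClusteringResult", sink: TextIO, dialect: str = "underscore"
) -> None:
    """One line per OTU: space-separated member labels, seed first."""
    for otu in result.otus:
        sink.write(" ".join(format_label(m, dialect) for m in otu.members))
        sink.write("\n")


def write_stats(result: "ClusteringResult", sink: TextIO) -> None:
    """Per-OTU statistics, tab-separated.

    Columns: unique amplicons, total copy number, seed identifier, seed
    abundance, number of singletons, maximum number of iterations
    (generations), maximum radius.
    """
    for otu in result.otus:
        s = otu.stats
        sink.write(
            f"{s.unique_count}\t{s.total_abundance}\t{s.seed_id}\t"
            f"{s.seed_abundance}\t{s.singleton_count}\t{s.max_generation}\t"
            f"{s.max_radius}\n"
        )


def compute_alignment_identities(
    result: "ClusteringResult", penalties: Optional[PenaltySystem] = None
) -> dict[str, tuple[float, str]]:
    """Percent identity and CIGAR of every non-seed member against its seed.

    Identity = matching columns / alignment columns * 100.  The CIGAR merges
    match and mismatch columns into M; identical sequences collapse to '='.
    """
    if penalties is None:
        penalties = transform_scoring(result.params.scoring)
    identities: dict[str, tuple[float, str]] = {}
    for otu in result.otus:
        for member in otu.members[1:]:
            r = align(otu.seed.sequence, member.sequence, penalties)
            if r.differences == 0:
                cigar = "="
            else:
                merged: list[tuple[int, str]] = []
                for m in re.finditer(r"(\d+)([MXDI])", r.cigar):
                    run, op = int(m.group(1)), m.group(2)
                    op = "M" if op in "MX" else op
                    if merged and merged[-1][1] == op:
                        merged[-1] = (merged[-1][0] + run, op)
                    else:
                        merged.append((run, op))
                cigar = "".join(f"{run}{op}" for run, op in merged)
            identity = 100.0 * r.matches / r.alignment_length
            identities[member.identifier] = (identity, cigar)
    return identities


def write_uclust(
    result: "ClusteringResult",
    identities: dict[str, tuple[float, str]],
    sink: TextIO,
    dialect: str = "underscore",
) -> None:
    """usearch-style .uc table: S/H records per cluster, then C summaries."""
    for number, otu in enumerate(result.otus):
        seed_label = format_label(otu.seed, dialect)
        sink.write(
            f"S\t{number}\t{len(otu.seed.sequence)}\t*\t*\t*\t*\t*\t"
            f"{seed_label}\t*\n"
        )
        for member in otu.members[1:]:
            identity, cigar = identities[member.identifier]
            sink.write(
                f"H\t{number}\t{len(member.sequence)}\t{identity:.1f}\t+\t0\t0\t"
                f"{cigar}\t{format_label(member, dialect)}\t{seed_label}\n"
            )
    for number, otu in enumerate(result.otus):
        sink.write(
            f"C\t{number}\t{len(otu.members)}\t*\t*\t*\t*\t*\t"
            f"{format_label(otu.seed, dialect)}\t*\n"
        )


def write_mothur(
    result: "ClusteringResult", d: int, sink: TextIO, dialect: str = "underscore"
) -> None:
    """mothur list format: label, OTU count, comma-joined members per OTU."""
    fields = [f"swarm_{d}", str(len(result.otus))]
    for otu in result.otus:
        fields.append(",".join(format_label(m, dialect) for m in otu.members))
    sink.write("\t".join(fields) + "\n")
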