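"""Exact-match read classification and the host-genome exclusion filter.

A read counts as a miRNA hit only on a perfect match over the entire length
of a catalog mature sequence — by default strict equality between the
adapter-trimmed read and the mature sequence (same length, zero
mismatches). Reads matching plant mature sequences are then screened
against the host genome: any read sharing a contiguous exact match of at
least 20 nt with either genome strand is considered host-genome derived and
excluded from the plant count. Animal-matching reads are never
genome-screened; reads matching both kingdoms are surfaced as
``ambiguous_kingdom`` and excluded from both totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .catalog import ANIMAL, PLANT, Catalog, MiRNARecord, normalize_rna

ANIMAL_MIRNA = "animal_mirna"
PLANT_MIRNA = "plant_mirna"
HOST_GENOME_DERIVED = "host_genome_derived"
AMBIGUOUS_KINGDOM = "ambiguous_kingdom"
UNASSIGNED = "unassigned"

CATEGORIES = (
    ANIMAL_MIRNA,
    PLANT_MIRNA,
    HOST_GENOME_DERIVED,
    AMBIGUOUS_KINGDOM,
    UNASSIGNED,
)

STRICT = "strict"
CONTAINS = "contains"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _dna(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def reverse_complement(sequence: str) -> str:
    return _dna(sequence).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A (possibly collapsed) small-RNA read with its multiplicity."""

    read_id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"{self.read_id}: count must be >= 1, got {self.count}")


class GenomeKmerIndex:
    """Set of all k-mers (default k=20) on both strands of a host genome.

    Membership of any length-k window of a read in this set is exactly the
    ">= k nt contiguous perfect match" criterion, because a longer shared
    block necessarily contains a shared k-mer.
    """

    def __init__(self, sequences: Iterable[str] = (), k: int = 20) -> None:
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.kmers: set[str] = set()
        for seq in sequences:
            self.add_sequence(seq)

    def add_sequence(self, sequence: str) -> None:
        k = self.k
        for strand in (_dna(sequence), reverse_complement(sequence)):
            self.kmers.update(strand[i : i + k] for i in range(len(strand) - k + 1))

    def __len__(self) -> int:
        return len(self.kmers)


def has_genome_match(read: "ReadRecord | str", genome_index: GenomeKmerIndex) -> bool:
    """True iff the read shares a >= k nt contiguous exact match with the genome.

    Both genome strands are indexed, so genomic provenance is recognised
    regardless of the strand the read was sequenced from. Reads shorter
    than k cannot satisfy the criterion and return False.
    """
    seq = _dna(read.sequence if isinstance(read, ReadRecord) else read)
    k = genome_index.k
    if len(seq) < k:
        return False
    kmers = genome_index.kmers
    return any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1))


@dataclass(frozen=True)
class Assignment:
    """Classification outcome for one (collapsed) read."""

    read_id: str
    sequence: str  # normalized RNA alphabet
    count: int
    category: str
    matched_records: tuple[MiRNARecord, ...] = ()
    family: Optional[str] = None
    clades: frozenset[str] = field(default_factory=frozenset)


def build_sequence_index(catalog: Catalog) -> dict[str, frozenset[MiRNARecord]]:
    """Exact-sequence lookup: normalized mature sequence -> matching records."""
    return dict(catalog.by_sequence)


def _matches(
    seq: str,
    index: Mapping[str, frozenset[MiRNARecord]],
    match_mode: str,
) -> frozenset[MiRNARecord]:
    hit = index.get(seq, frozenset())
    if hit or match_mode == STRICT:
        return hit
    if match_mode != CONTAINS:
        raise ValueError(f"unknown match mode {match_mode!r}")
    # contains mode: accept a read that carries the full mature sequence
    # with untrimmed flanking bases
    found: set[MiRNARecord] = set()
    for mature, recs in index.items():
        if mature in seq:
            found.update(recs)
    return frozenset(found)


def classify_read(
    read: ReadRecord,
    index: Mapping[str, frozenset[MiRNARecord]],
    genome_index: Optional[GenomeKmerIndex] = None,
    match_mode: str = STRICT,
) -> Assignment:
    """Classify one read against the catalog and the host-genome filter."""
    if not read.sequence:
        raise ValueError(f"{read.read_id}: empty read sequence")
    seq = normalize_rna(read.sequence)
    matched = _matches(seq, index, match_mode)
    kingdoms = {rec.kingdom for rec in matched}

    if not matched:
        category = UNASSIGNED
    elif kingdoms == {PLANT, ANIMAL}:
        category = AMBIGUOUS_KINGDOM
    elif kingdoms == {ANIMAL}:
        category = ANIMAL_MIRNA
    else:
        category = PLANT_MIRNA
        if genome_index is not None and has_genome_match(read, genome_index):
            category = HOST_GENOME_DERIVED

    family: Optional[str] = None
    clades: frozenset[str] = frozenset()
    if category in (PLANT_MIRNA, HOST_GENOME_DERIVED, ANIMAL_MIRNA):
        families = sorted({rec.family for rec in matched})
        family = families[0]
        clades = frozenset(
            rec.clade for rec in matched if rec.kingdom == PLANT
        )
    elif category == AMBIGUOUS_KINGDOM:
        clades = frozenset(rec.clade for rec in matched if rec.kingdom == PLANT)

    return Assignment(
        read_id=read.read_id,
        sequence=seq,
        count=read.count,
        category=category,
        matched_records=tuple(sorted(matched)),
        family=family,
        clades=clades,
    )


def classify_library(
    reads: Sequence[ReadRecord],
    index: Mapping[str, frozenset[MiRNARecord]],
    genome_index: Optional[GenomeKmerIndex] = None,
    match_mode: str = STRICT,
) -> list[Assignment]:
    """Classify every read of a library, preserving order and multiplicity."""
    out: list[Assignment] = []
    for read in reads:
        try:
            out.append(classify_read(read, index, genome_index, match_mode))
        except ValueError as exc:
            raise ValueError(f"read {read.read_id!r}: {exc}") from exc
    assert sum(a.count for a in out) == sum(r.count for r in reads)
    return out
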