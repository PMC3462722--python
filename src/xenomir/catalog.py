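"""Mature-miRNA reference catalog: parsing, annotation and sequence queries.

The catalog is the reference against which every read is classified. Each
entry is a mature miRNA with a miRBase-style identifier
(``<species>-<family><variant>``, e.g. ``osa-miR168a``), annotated with its
kingdom (plant or animal) and, for plants, the flowering-plant clade
(monocot or dicot) of the carrying species. Clade annotation is what lets a
sequence variant shared only by monocots — such as the monocot miR168
variant — pinpoint the botanical origin of a read found in an animal
library.

Species metadata is an explicit input (a three-column TSV) rather than a
hard-coded table, because registry species lists drift between releases.
"""

from __future__ import annotations

import io
import re
from collections import defaultdict
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, TextIO, Union

import pandas as pd
from Bio import SeqIO

PLANT = "plant"
ANIMAL = "animal"
MONOCOT = "monocot"
DICOT = "dicot"
NOT_APPLICABLE = "not_applicable"

KINGDOMS = frozenset({PLANT, ANIMAL})
CLADES = frozenset({MONOCOT, DICOT, NOT_APPLICABLE})

_RNA_ALPHABET = frozenset("ACGU")
# family name stems that may follow the species prefix in a miRBase id
_FAMILY_STEM_RE = re.compile(r"^(mir|let|lin|bantam|lsy|iab)", re.IGNORECASE)
_ARM_RE = re.compile(r"(-[35]p)$")
_LOCUS_RE = re.compile(r"^(.*\d[a-z]*)-\d+$")
_VARIANT_RE = re.compile(r"^(.*\d)[a-z]$")

PathOrHandle = Union[str, PathLike, TextIO]


class CatalogError(ValueError):
    """Malformed catalog input (bad header, bad alphabet, unknown species)."""


def normalize_rna(sequence: str) -> str:
    """Upper-case a sequence and convert T to U (DNA dialects accepted)."""
    return sequence.upper().replace("T", "U")


def family_of(mirna_id: str) -> str:
    """Normalize a miRNA identifier to its family key.

    The family key is the identifier with the species prefix, any single
    trailing lowercase variant letter, and any trailing ``-<n>`` locus
    suffix removed; arm suffixes ``-3p``/``-5p`` are retained because the
    two arms are distinct mature products. The function is idempotent:
    applying it to a family key returns the key unchanged.

    >>> family_of("zma-miR168a")
    'miR168'
    >>> family_of("dme-miR-8-5p")
    'miR-8-5p'
    """
    core = mirna_id.strip()
    if "-" in core:
        prefix, rest = core.split("-", 1)
        # strip the species prefix only when what follows looks like a
        # family name; this keeps keys like "miR-8-5p" as fixed points
        if prefix.isalnum() and prefix == prefix.lower() and _FAMILY_STEM_RE.match(rest):
            core = rest
    elif not _FAMILY_STEM_RE.match(core):
        raise CatalogError(f"cannot derive a miRNA family from {mirna_id!r}")

    arm = ""
    m = _ARM_RE.search(core)
    if m:
        arm = m.group(1)
        core = core[: m.start()]
    m = _LOCUS_RE.match(core)
    if m:
        core = m.group(1)
    m = _VARIANT_RE.match(core)
    if m:
        core = m.group(1)
    return core + arm


@dataclass(frozen=True, order=True)
class MiRNARecord:
    """One catalog entry: a mature miRNA with its taxonomy annotations."""

    mirna_id: str
    species_code: str
    family: str
    kingdom: str
    clade: str
    sequence: str

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise CatalogError(f"{self.mirna_id}: unknown kingdom {self.kingdom!r}")
        if self.clade not in CLADES:
            raise CatalogError(f"{self.mirna_id}: unknown clade {self.clade!r}")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise CatalogError(
                f"{self.mirna_id}: non-ACGU characters in sequence: {sorted(bad)}"
            )


class Catalog:
    """An annotated set of mature miRNAs with exact-sequence lookup."""

    def __init__(
        self,
        records: Iterable[MiRNARecord],
        species_meta: Mapping[str, tuple[str, str]],
    ) -> None:
        self.records: list[MiRNARecord] = list(records)
        self.species_meta: dict[str, tuple[str, str]] = dict(species_meta)
        self.by_sequence: dict[str, frozenset[MiRNARecord]] = {}
        grouped: dict[str, set[MiRNARecord]] = defaultdict(set)
        for rec in self.records:
            if rec.species_code not in self.species_meta:
                raise CatalogError(
                    f"{rec.mirna_id}: species code {rec.species_code!r} missing "
                    "from species metadata"
                )
            grouped[rec.sequence].add(rec)
        self.by_sequence = {seq: frozenset(recs) for seq, recs in grouped.items()}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lookup(self, sequence: str) -> frozenset[MiRNARecord]:
        """All records whose mature sequence equals ``sequence`` exactly."""
        return self.by_sequence.get(normalize_rna(sequence), frozenset())

    def plant_records(self) -> list[MiRNARecord]:
        return [r for r in self.records if r.kingdom == PLANT]

    def animal_records(self) -> list[MiRNARecord]:
        return [r for r in self.records if r.kingdom == ANIMAL]

    def families_of_species(self, species_code: str) -> dict[str, str]:
        """Map family -> one mature sequence for a given species."""
        out: dict[str, str] = {}
        for rec in sorted(self.records):
            if rec.species_code == species_code and rec.family not in out:
                out[rec.family] = rec.sequence
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": r.mirna_id,
                "species_code": r.species_code,
                "family": r.family,
                "kingdom": r.kingdom,
                "clade": r.clade,
                "sequence": r.sequence,
            }
            for r in sorted(self.records)
        ]
        return pd.DataFrame(
            rows,
            columns=["mirna_id", "species_code", "family", "kingdom", "clade", "sequence"],
        )

    def write_fasta(self, path: Union[str, PathLike, TextIO]) -> None:
        handle = path if hasattr(path, "write") else open(path, "w")
        try:
            for rec in sorted(self.records):
                handle.write(f">{rec.mirna_id}\n{rec.sequence}\n")
        finally:
            if not hasattr(path, "write"):
                handle.close()


def load_species_meta(source: PathOrHandle) -> dict[str, tuple[str, str]]:
    """Read the species metadata TSV (species_code, kingdom, clade)."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    required = {"species_code", "kingdom", "clade"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"species metadata missing columns: {sorted(missing)}")
    meta: dict[str, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        if row.kingdom not in KINGDOMS:
            raise CatalogError(f"{row.species_code}: bad kingdom {row.kingdom!r}")
        if row.clade not in CLADES:
            raise CatalogError(f"{row.species_code}: bad clade {row.clade!r}")
        meta[row.species_code] = (row.kingdom, row.clade)
    return meta


def species_code_of(mirna_id: str) -> str:
    """The species prefix: text before the first dash of the identifier."""
    if "-" not in mirna_id:
        raise CatalogError(f"malformed miRNA id (no '-' separator): {mirna_id!r}")
    return mirna_id.split("-", 1)[0]


def parse_mature_fasta(
    fasta_source: PathOrHandle,
    species_meta: Mapping[str, tuple[str, str]],
) -> Catalog:
    """Parse a mature-miRNA FASTA into an annotated :class:`Catalog`.

    Headers follow the miRBase dialect: the first whitespace-delimited token
    is the miRNA identifier. Sequences may be in DNA or RNA alphabet; T is
    converted to U on ingest. Duplicate (id, sequence) pairs collapse to one
    record. Unknown species codes are a load-time error so that kingdom and
    clade annotation is guaranteed complete.
    """
    if isinstance(fasta_source, str) and fasta_source.lstrip().startswith(">"):
        handle: TextIO = io.StringIO(fasta_source)
    elif hasattr(fasta_source, "read"):
        handle = fasta_source  # type: ignore[assignment]
    else:
        handle = open(Path(fasta_source))

    seen: set[tuple[str, str]] = set()
    records: list[MiRNARecord] = []
    try:
        for entry in SeqIO.parse(handle, "fasta"):
            mirna_id = entry.id
            seq = normalize_rna(str(entry.seq))
            bad = set(seq) - _RNA_ALPHABET
            if bad:
                raise CatalogError(
                    f"{mirna_id}: sequence contains non-ACGU/T characters {sorted(bad)}"
                )
            code = species_code_of(mirna_id)
            if code not in species_meta:
                raise CatalogError(
                    f"{mirna_id}: species code {code!r} not in species metadata"
                )
            key = (mirna_id, seq)
            if key in seen:
                continue
            seen.add(key)
            kingdom, clade = species_meta[code]
            records.append(
                MiRNARecord(
                    mirna_id=mirna_id,
                    species_code=code,
                    family=family_of(mirna_id),
                    kingdom=kingdom,
                    clade=clade,
                    sequence=seq,
                )
            )
    finally:
        if handle is not fasta_source:
            handle.close()
    return Catalog(records, species_meta)


def hamming_distance(seq_a: str, seq_b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"hamming distance undefined for unequal lengths "
            f"({len(seq_a)} vs {len(seq_b)})"
        )
    return sum(a != b for a, b in zip(seq_a, seq_b))


def clades_of_sequence(sequence: str, catalog: Catalog) -> set[str]:
    """Clades of all plant records whose mature sequence matches exactly.

    An empty set means the sequence is absent from the plant side of the
    catalog; a single-clade result makes the sequence clade-diagnostic.
    """
    return {
        rec.clade for rec in catalog.lookup(sequence) if rec.kingdom == PLANT
    }


def cross_kingdom_identical(
    catalog: Catalog,
) -> list[tuple[str, list[MiRNARecord], list[MiRNARecord]]]:
    """Mature sequences carried by at least one plant AND one animal record.

    A non-empty result means kingdom assignment by exact sequence identity
    is ambiguous for those sequences; such reads are surfaced explicitly by
    the classifier rather than silently assigned.
    """
    out = []
    for seq in sorted(catalog.by_sequence):
        recs = catalog.by_sequence[seq]
        plants = sorted(r for r in recs if r.kingdom == PLANT)
        animals = sorted(r for r in recs if r.kingdom == ANIMAL)
        if plants and animals:
            out.append((seq, plants, animals))
    return out
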