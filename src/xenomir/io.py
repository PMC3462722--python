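"""Readers and writers for the flat interchange formats.

Reads arrive as FASTQ (qualities ignored) or FASTA, optionally collapsed
with the ``_xN`` multiplicity suffix dialect in the identifier. All stage
outputs are flat TSV with a versioned ``# xenomir-schema:`` comment header
so files can be validated when fed back into a later stage; an optional
provenance line carries the pipeline config hash and seed.
"""

from __future__ import annotations

import re
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .catalog import Catalog, MiRNARecord
from .contamination import ContaminationReport, LibraryInfo, RunManifest
from .matcher import Assignment, ReadRecord

_COUNT_SUFFIX = re.compile(r"^(?P<base>.*)_x(?P<count>\d+)$")

SCHEMAS = {
    "assignments": "xenomir/assignments/v1",
    "profiles": "xenomir/profiles/v1",
    "catalog": "xenomir/catalog/v1",
    "manifest": "xenomir/manifest/v1",
    "contamination": "xenomir/contamination/v1",
}

ASSIGNMENT_COLUMNS = [
    "read_id",
    "count",
    "category",
    "family",
    "clades",
    "matched_ids",
    "sequence",
]
MANIFEST_COLUMNS = ["run_id", "library_id", "organism", "role", "diet", "comultiplexed"]


class SchemaError(ValueError):
    """Interchange file does not carry the expected columns."""


def parse_collapsed_id(read_id: str) -> tuple[str, int]:
    """Split the ``_xN`` count suffix off a collapsed read id (default 1)."""
    m = _COUNT_SUFFIX.match(read_id)
    if m:
        return m.group("base"), int(m.group("count"))
    return read_id, 1


def load_reads(path: Union[str, PathLike], fmt: Optional[str] = None) -> list[ReadRecord]:
    """Load a read library from FASTA (``_xN`` dialect) or FASTQ."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads: list[ReadRecord] = []
    for entry in SeqIO.parse(str(path), fmt):
        if fmt == "fasta":
            _, count = parse_collapsed_id(entry.id)
        else:
            count = 1
        reads.append(
            ReadRecord(read_id=entry.id, sequence=str(entry.seq).upper(), count=count)
        )
    return reads


def write_reads_fasta(reads: Sequence[ReadRecord], path: Union[str, PathLike]) -> None:
    """Write reads as collapsed FASTA (count carried in the ``_xN`` suffix)."""
    with open(path, "w") as fh:
        for read in reads:
            base, embedded = parse_collapsed_id(read.read_id)
            read_id = read.read_id if embedded == read.count else f"{base}_x{read.count}"
            fh.write(f">{read_id}\n{read.sequence}\n")


def load_genome_fasta(path: Union[str, PathLike]) -> list[str]:
    """All sequences of a (multi-record) genome FASTA, upper-cased DNA."""
    return [
        str(entry.seq).upper().replace("U", "T")
        for entry in SeqIO.parse(str(path), "fasta")
    ]


def _write_tsv(
    df: pd.DataFrame, path: Union[str, PathLike], schema: str, provenance: Optional[str]
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# xenomir-schema: {SCHEMAS[schema]}\n")
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Union[str, PathLike], schema: str, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"library_id": str})
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {sorted(missing)} for {SCHEMAS[schema]}"
        )
    return df


def write_assignments(
    assignments: Sequence[Assignment],
    path: Union[str, PathLike],
    provenance: Optional[str] = None,
) -> None:
    rows = [
        {
            "read_id": a.read_id,
            "count": a.count,
            "category": a.category,
            "family": a.family or "",
            "clades": ",".join(sorted(a.clades)),
            "matched_ids": ",".join(r.mirna_id for r in a.matched_records),
            "sequence": a.sequence,
        }
        for a in assignments
    ]
    _write_tsv(pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS), path, "assignments", provenance)


def load_assignments(path: Union[str, PathLike]) -> list[Assignment]:
    """Reload per-read assignments (without catalog record objects)."""
    df = _read_tsv(path, "assignments", ASSIGNMENT_COLUMNS)
    out: list[Assignment] = []
    for row in df.itertuples(index=False):
        family = row.family if isinstance(row.family, str) and row.family else None
        clades = (
            frozenset(str(row.clades).split(","))
            if isinstance(row.clades, str) and row.clades
            else frozenset()
        )
        out.append(
            Assignment(
                read_id=str(row.read_id),
                sequence=str(row.sequence),
                count=int(row.count),
                category=str(row.category),
                matched_records=(),
                family=family,
                clades=clades,
            )
        )
    return out


def write_catalog_summary(
    catalog: Catalog, path: Union[str, PathLike], provenance: Optional[str] = None
) -> None:
    _write_tsv(catalog.to_dataframe(), path, "catalog", provenance)


def write_profiles_table(
    table: pd.DataFrame, path: Union[str, PathLike], provenance: Optional[str] = None
) -> None:
    _write_tsv(table, path, "profiles", provenance)


def load_species_meta_tsv(path: Union[str, PathLike]) -> dict[str, tuple[str, str]]:
    from .catalog import load_species_meta

    return load_species_meta(path)


def write_species_meta(
    meta: Mapping[str, tuple[str, str]], path: Union[str, PathLike]
) -> None:
    with open(path, "w") as fh:
        fh.write("species_code\tkingdom\tclade\n")
        for code in sorted(meta):
            kingdom, clade = meta[code]
            fh.write(f"{code}\t{kingdom}\t{clade}\n")


def write_manifest(
    manifest: RunManifest, path: Union[str, PathLike], provenance: Optional[str] = None
) -> None:
    rows = [
        {
            "run_id": manifest.run_id,
            "library_id": lib.library_id,
            "organism": lib.organism,
            "role": lib.role,
            "diet": lib.diet or "",
            "comultiplexed": manifest.comultiplexed,
        }
        for lib in manifest.libraries
    ]
    _write_tsv(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), path, "manifest", provenance)


def load_manifest(path: Union[str, PathLike]) -> RunManifest:
    df = _read_tsv(path, "manifest", MANIFEST_COLUMNS)
    if df.empty:
        raise SchemaError(f"{path}: empty run manifest")
    run_ids = df["run_id"].unique()
    if len(run_ids) != 1:
        raise SchemaError(f"{path}: expected a single run_id, got {list(run_ids)}")
    libraries = [
        LibraryInfo(
            library_id=str(row.library_id),
            organism=str(row.organism),
            role=str(row.role),
            diet=str(row.diet) if isinstance(row.diet, str) and row.diet else None,
        )
        for row in df.itertuples(index=False)
    ]
    comultiplexed = bool(df["comultiplexed"].iloc[0])
    return RunManifest(run_id=str(run_ids[0]), libraries=libraries, comultiplexed=comultiplexed)


def contamination_report_table(report: ContaminationReport) -> pd.DataFrame:
    rows = []
    for lib_id in sorted(report.per_library):
        d = report.per_library[lib_id]
        rows.append(
            {
                "run_id": report.run_id,
                "library_id": lib_id,
                "monocot_pct": d.clade_breakdown.get("monocot", 0.0),
                "dicot_pct": d.clade_breakdown.get("dicot", 0.0),
                "unresolved_pct": d.clade_breakdown.get("unresolved", 0.0),
                "similarity_to_diet": d.similarity_to_diet,
                "similarity_to_pooled_run": d.similarity_to_pooled_run,
                "verdict": d.verdict,
                "bleed_estimate": d.bleed_estimate,
                "notes": ";".join(d.notes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "library_id",
            "monocot_pct",
            "dicot_pct",
            "unresolved_pct",
            "similarity_to_diet",
            "similarity_to_pooled_run",
            "verdict",
            "bleed_estimate",
            "notes",
        ],
    )


def write_contamination_report(
    report: ContaminationReport,
    path: Union[str, PathLike],
    provenance: Optional[str] = None,
) -> None:
    _write_tsv(contamination_report_table(report), path, "contamination", provenance)
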