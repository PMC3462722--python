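"""End-to-end orchestration: catalog -> classify -> profile -> diagnose.

Stages run in a fixed order and exchange flat TSV files, so each stage can
also be run standalone on the interchange files (the CLI subcommands);
composing the stages is byte-identical to a monolithic run because both
paths call the same stage functions with the same provenance stamp. A
machine-readable run log records versions, the seed, thresholds, the
config hash, and per-stage read-count conservation checks; any
conservation violation aborts the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy
import pandas
import scipy
import yaml

from . import __version__
from . import io as xio
from .catalog import Catalog, load_species_meta, parse_mature_fasta
from .contamination import (
    DEFAULT_CLADE_THRESHOLD,
    DEFAULT_DECISION_MARGIN,
    DEFAULT_MARKER_MIN_ABUNDANCE,
    RunManifest,
    diagnose_run,
)
from .matcher import (
    STRICT,
    Assignment,
    GenomeKmerIndex,
    build_sequence_index,
    classify_library,
)
from .profiler import (
    DEFAULT_SIGNIFICANCE_PCT,
    flag_significant,
    profile_library,
    profiles_to_table,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed (bad config, conservation violation, ...)."""


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    catalog_path: Path
    species_meta_path: Path
    manifest_path: Path
    reads: dict[str, Path]  # library_id -> read file
    genomes: dict[str, Path] = field(default_factory=dict)  # organism -> FASTA
    match_mode: str = STRICT
    significance_pct: float = DEFAULT_SIGNIFICANCE_PCT
    decision_margin: float = DEFAULT_DECISION_MARGIN
    clade_threshold_pct: float = DEFAULT_CLADE_THRESHOLD
    marker_min_abundance: float = DEFAULT_MARKER_MIN_ABUNDANCE
    out_dir: Path = Path("xenomir_out")
    seed: int = 0
    config_hash: str = "unhashed"

    @property
    def provenance(self) -> str:
        return f"config_sha256={self.config_hash} seed={self.seed}"

    @classmethod
    def from_yaml(
        cls,
        path: str | Path,
        out_dir: Optional[str | Path] = None,
        seed: Optional[int] = None,
        match_mode: Optional[str] = None,
        significance_pct: Optional[float] = None,
    ) -> "PipelineConfig":
        path = Path(path)
        raw_bytes = path.read_bytes()
        raw = yaml.safe_load(raw_bytes) or {}
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        manifest_path = resolve(raw["manifest"])
        reads_cfg = raw.get("reads")
        if reads_cfg:
            reads = {lib: resolve(p) for lib, p in reads_cfg.items()}
        elif "reads_dir" in raw:
            reads_dir = resolve(raw["reads_dir"])
            manifest = xio.load_manifest(manifest_path)
            reads = {}
            for lib in manifest.libraries:
                for suffix in (".fasta", ".fa", ".fastq", ".fq"):
                    candidate = reads_dir / f"{lib.library_id}{suffix}"
                    if candidate.exists():
                        reads[lib.library_id] = candidate
                        break
                else:
                    raise PipelineError(
                        f"no read file for library {lib.library_id!r} in {reads_dir}"
                    )
        else:
            raise PipelineError("config must define 'reads' or 'reads_dir'")

        thresholds = raw.get("thresholds", {})
        cfg = cls(
            catalog_path=resolve(raw["catalog"]),
            species_meta_path=resolve(raw["species_meta"]),
            manifest_path=manifest_path,
            reads=reads,
            genomes={org: resolve(p) for org, p in raw.get("genomes", {}).items()},
            match_mode=match_mode or raw.get("match_mode", STRICT),
            significance_pct=(
                significance_pct
                if significance_pct is not None
                else float(thresholds.get("significance_pct", DEFAULT_SIGNIFICANCE_PCT))
            ),
            decision_margin=float(
                thresholds.get("decision_margin", DEFAULT_DECISION_MARGIN)
            ),
            clade_threshold_pct=float(
                thresholds.get("clade_threshold_pct", DEFAULT_CLADE_THRESHOLD)
            ),
            marker_min_abundance=float(
                thresholds.get("marker_min_abundance", DEFAULT_MARKER_MIN_ABUNDANCE)
            ),
            out_dir=Path(out_dir) if out_dir else Path(raw.get("out_dir", "xenomir_out")),
            seed=seed if seed is not None else int(raw.get("seed", 0)),
            config_hash=hashlib.sha256(raw_bytes).hexdigest()[:16],
        )
        for p in [cfg.catalog_path, cfg.species_meta_path, cfg.manifest_path, *cfg.reads.values(), *cfg.genomes.values()]:
            if not Path(p).exists():
                raise PipelineError(f"configured path does not exist: {p}")
        return cfg


def stage_catalog(config: PipelineConfig) -> Catalog:
    """Parse and annotate the catalog; write the catalog summary TSV."""
    meta = load_species_meta(config.species_meta_path)
    catalog = parse_mature_fasta(config.catalog_path, meta)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    xio.write_catalog_summary(
        catalog, config.out_dir / "catalog_summary.tsv", config.provenance
    )
    return catalog


def stage_classify(
    config: PipelineConfig, catalog: Catalog, manifest: RunManifest
) -> tuple[dict[str, list[Assignment]], dict]:
    """Classify every library; write per-library assignment TSVs."""
    index = build_sequence_index(catalog)
    genome_indexes: dict[str, GenomeKmerIndex] = {}
    for organism, path in config.genomes.items():
        genome_indexes[organism] = GenomeKmerIndex(xio.load_genome_fasta(path), k=20)

    assignments: dict[str, list[Assignment]] = {}
    log: dict = {"libraries": {}, "genome_screen_skipped": []}
    out = config.out_dir / "assignments"
    out.mkdir(parents=True, exist_ok=True)
    for lib in manifest.libraries:
        lib_id = lib.library_id
        if lib_id not in config.reads:
            raise PipelineError(f"no read file configured for library {lib_id!r}")
        reads = xio.load_reads(config.reads[lib_id])
        genome_index = genome_indexes.get(lib.organism)
        if genome_index is None and lib.role == "animal_sample":
            log["genome_screen_skipped"].append(lib_id)
        result = classify_library(
            reads, index, genome_index, match_mode=config.match_mode
        )
        n_in = sum(r.count for r in reads)
        n_out = sum(a.count for a in result)
        log["libraries"][lib_id] = {
            "reads_in": n_in,
            "reads_out": n_out,
            "conserved": n_in == n_out,
            "genome_screened": genome_index is not None,
        }
        if n_in != n_out:
            raise PipelineError(
                f"read-count conservation violated for {lib_id}: {n_in} != {n_out}"
            )
        xio.write_assignments(result, out / f"{lib_id}.tsv", config.provenance)
        assignments[lib_id] = result
    return assignments, log


def stage_profile(
    config: PipelineConfig,
    assignments: dict[str, list[Assignment]],
    manifest: RunManifest,
) -> pandas.DataFrame:
    """Aggregate assignments into per-library profiles; write report TSVs."""
    profiles = []
    for lib in manifest.libraries:
        profile = profile_library(assignments[lib.library_id], lib.library_id)
        if not config.genomes.get(lib.organism) and lib.role == "animal_sample":
            profile.flags.append("genome_screen_skipped")
        profiles.append(profile)
    table = profiles_to_table(profiles)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    xio.write_profiles_table(table, config.out_dir / "profiles.tsv", config.provenance)
    significant = flag_significant(profiles, config.significance_pct)
    xio.write_profiles_table(
        profiles_to_table(significant),
        config.out_dir / "significant.tsv",
        config.provenance,
    )
    family_maps = {
        p.library_id: {
            "plant": p.plant_family_counts,
            "animal": p.animal_family_counts,
        }
        for p in profiles
    }
    with open(config.out_dir / "family_counts.json", "w") as fh:
        json.dump(family_maps, fh, indent=1, sort_keys=True)
    return table


def stage_diagnose(
    config: PipelineConfig,
    catalog: Catalog,
    assignments: dict[str, list[Assignment]],
    manifest: RunManifest,
):
    """Run contamination diagnostics; write the report TSV and JSON detail."""
    report = diagnose_run(
        manifest,
        assignments,
        catalog,
        decision_margin=config.decision_margin,
        clade_threshold_pct=config.clade_threshold_pct,
        marker_min_abundance=config.marker_min_abundance,
    )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    xio.write_contamination_report(
        report, config.out_dir / "contamination.tsv", config.provenance
    )
    detail = {
        "run_id": report.run_id,
        "provenance": config.provenance,
        "marker_traces": [
            {
                "marker_sequence": t.marker_sequence,
                "per_library_counts": t.per_library_counts,
                "source_libraries": sorted(t.source_libraries),
            }
            for t in report.marker_traces
        ],
        "per_library": {
            lib_id: {
                "clade_breakdown": d.clade_breakdown,
                "similarity_to_diet": d.similarity_to_diet,
                "similarity_to_pooled_run": d.similarity_to_pooled_run,
                "verdict": d.verdict,
                "bleed_estimate": d.bleed_estimate,
                "notes": d.notes,
            }
            for lib_id, d in sorted(report.per_library.items())
        },
    }
    with open(config.out_dir / "contamination.json", "w") as fh:
        json.dump(detail, fh, indent=1, sort_keys=True)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and write the run log; returns the log."""
    log: dict = {
        "xenomir_version": __version__,
        "python": sys.version.split()[0],
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "match_mode": config.match_mode,
        "thresholds": {
            "significance_pct": config.significance_pct,
            "decision_margin": config.decision_margin,
            "clade_threshold_pct": config.clade_threshold_pct,
            "marker_min_abundance": config.marker_min_abundance,
        },
        "stages": [],
    }
    try:
        manifest = xio.load_manifest(config.manifest_path)
        catalog = stage_catalog(config)
        log["stages"].append("catalog")
        assignments, classify_log = stage_classify(config, catalog, manifest)
        log["classify"] = classify_log
        log["stages"].append("classify")
        stage_profile(config, assignments, manifest)
        log["stages"].append("profile")
        stage_diagnose(config, catalog, assignments, manifest)
        log["stages"].append("diagnose")
        log["status"] = "ok"
    except Exception as exc:
        log["status"] = "failed"
        log["error"] = str(exc)
        config.out_dir.mkdir(parents=True, exist_ok=True)
        with open(config.out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
        raise
    with open(config.out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return log


def pipeline_config_for_simulated_run(
    sim_dir: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    **thresholds,
) -> PipelineConfig:
    """Convenience: a PipelineConfig pointing at a written simulated run."""
    sim_dir = Path(sim_dir)
    manifest = xio.load_manifest(sim_dir / "manifest.tsv")
    reads = {
        lib.library_id: sim_dir / "reads" / f"{lib.library_id}.fasta"
        for lib in manifest.libraries
    }
    genomes = {
        p.stem: p for p in sorted((sim_dir / "genomes").glob("*.fasta"))
    } if (sim_dir / "genomes").exists() else {}
    return PipelineConfig(
        catalog_path=sim_dir / "catalog.fasta",
        species_meta_path=sim_dir / "species_meta.tsv",
        manifest_path=sim_dir / "manifest.tsv",
        reads=reads,
        genomes=genomes,
        out_dir=Path(out_dir),
        seed=seed,
        config_hash=hashlib.sha256(str(sorted(dataclasses.asdict(
            RunManifest(run_id=manifest.run_id, libraries=manifest.libraries,
                        comultiplexed=manifest.comultiplexed)
        ).items())).encode()).hexdigest()[:16],
        **thresholds,
    )
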