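"""Clade-of-origin attribution and multiplexed-run contamination diagnostics.

Three lines of evidence distinguish dietary uptake of plant miRNAs from
sequencing cross-contamination within a multiplexed run:

* **Clade breakdown** — clade-diagnostic sequence variants (e.g. the
  monocot and dicot miR168 variants, two nucleotides apart) attribute each
  plant-matching read to monocots or dicots; a dicot-fed animal whose
  plant reads are overwhelmingly monocot-variant is inconsistent with diet.
* **Profile similarity** — a Spearman rank correlation (on log1p counts
  over the union of plant families) compares an animal library's plant
  miRNA profile with its declared diet's profile and with the pooled
  profile of all co-multiplexed plant libraries. A library that resembles
  the pooled run more than its own diet points to inter-library bleed.
* **Marker tracing** — a sequence essentially private to one source
  library (e.g. a lettuce-specific small RNA) appearing at low counts in
  every co-multiplexed library, and at zero in libraries from other runs,
  is direct evidence of bleed and yields a per-run bleed-rate estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .catalog import Catalog, clades_of_sequence, normalize_rna
from .matcher import PLANT_MIRNA, UNASSIGNED, Assignment

PLANT_SOURCE = "plant_source"
ANIMAL_SAMPLE = "animal_sample"

DIET_CONSISTENT = "diet_consistent"
CONTAMINATION_SUSPECTED = "contamination_suspected"
INCONCLUSIVE = "inconclusive"

UNRESOLVED = "unresolved"

DEFAULT_DECISION_MARGIN = 0.2
DEFAULT_CLADE_THRESHOLD = 50.0  # percent of clade-assignable reads
DEFAULT_MARKER_MIN_ABUNDANCE = 1e-4


@dataclass(frozen=True)
class LibraryInfo:
    library_id: str
    organism: str
    role: str  # plant_source | animal_sample
    diet: Optional[str] = None  # species code of declared diet, if any


@dataclass
class RunManifest:
    """Which libraries were sequenced together, and what each sample ate."""

    run_id: str
    libraries: list[LibraryInfo]
    comultiplexed: bool = True

    def __post_init__(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        if len(ids) != len(set(ids)):
            raise ValueError(f"run {self.run_id}: duplicate library ids")

    def by_id(self, library_id: str) -> LibraryInfo:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise KeyError(library_id)

    def plant_sources(self) -> list[LibraryInfo]:
        return [l for l in self.libraries if l.role == PLANT_SOURCE]

    def animal_samples(self) -> list[LibraryInfo]:
        return [l for l in self.libraries if l.role == ANIMAL_SAMPLE]


@dataclass
class MarkerTrace:
    """Per-library exact-match counts of one library-specific marker."""

    marker_sequence: str
    per_library_counts: dict[str, int]
    source_libraries: set[str]


@dataclass
class LibraryDiagnosis:
    library_id: str
    clade_breakdown: dict[str, float]
    similarity_to_diet: Optional[float]
    similarity_to_pooled_run: Optional[float]
    verdict: str
    notes: list[str] = field(default_factory=list)
    bleed_estimate: Optional[float] = None


@dataclass
class ContaminationReport:
    run_id: str
    per_library: dict[str, LibraryDiagnosis]
    marker_traces: list[MarkerTrace] = field(default_factory=list)


def clade_breakdown(
    assignments: Sequence[Assignment],
    catalog: Catalog,
    family: Optional[str] = None,
) -> dict[str, float]:
    """Percent of plant-matching reads attributable to each plant clade.

    Each distinct matched sequence variant is assigned the clade set of the
    plant records carrying it; variants carried by both clades (or by
    none — possible only in degenerate catalogs) count as ``unresolved``
    rather than being split fractionally. Restricting to one family
    reproduces per-family breakdowns such as the monocot share of miR168.
    Returns an empty map when no qualifying reads exist.
    """
    counts: dict[str, int] = {}
    variant_counts: dict[str, int] = {}
    for a in assignments:
        if a.category != PLANT_MIRNA:
            continue
        if family is not None and a.family != family:
            continue
        variant_counts[a.sequence] = variant_counts.get(a.sequence, 0) + a.count
    for seq, n in variant_counts.items():
        clades = clades_of_sequence(seq, catalog)
        key = next(iter(clades)) if len(clades) == 1 else UNRESOLVED
        counts[key] = counts.get(key, 0) + n
    total = sum(counts.values())
    if total == 0:
        return {}
    return {clade: 100.0 * n / total for clade, n in sorted(counts.items())}


def profile_similarity(
    family_counts_a: Mapping[str, int],
    family_counts_b: Mapping[str, int],
) -> float:
    """Spearman rank correlation of two family-count profiles.

    Computed over the union of family keys (absent families count 0) on
    log1p-transformed counts, so the score is invariant to library size
    and to any monotone rescaling of the counts. Requires at least 3
    families in the union.
    """
    keys = sorted(set(family_counts_a) | set(family_counts_b))
    if len(keys) < 3:
        raise ValueError(
            f"profile similarity needs >= 3 families in the union, got {len(keys)}"
        )
    a = np.log1p([float(family_counts_a.get(k, 0)) for k in keys])
    b = np.log1p([float(family_counts_b.get(k, 0)) for k in keys])
    if np.all(a == a[0]) or np.all(b == b[0]):
        # rank correlation undefined for a constant profile
        return 1.0 if np.array_equal(a, b) else 0.0
    rho = stats.spearmanr(a, b).statistic
    return float(rho) if math.isfinite(rho) else 0.0


def trace_marker(
    marker_sequence: str,
    libraries_assignments: Mapping[str, Sequence[Assignment]],
    manifest: RunManifest,
    source_min_abundance: float = DEFAULT_MARKER_MIN_ABUNDANCE,
) -> MarkerTrace:
    """Count exact matches of a marker sequence in every library.

    Source libraries are those where the marker's relative abundance
    exceeds ``source_min_abundance``; any other library with nonzero
    counts has received the marker from elsewhere (bleed, if
    co-multiplexed). A marker absent from every library is unusable.
    """
    marker = normalize_rna(marker_sequence)
    counts: dict[str, int] = {}
    sources: set[str] = set()
    for lib in manifest.libraries:
        assignments = libraries_assignments.get(lib.library_id, ())
        total = sum(a.count for a in assignments)
        n = sum(a.count for a in assignments if a.sequence == marker)
        counts[lib.library_id] = n
        if total > 0 and n / total > source_min_abundance:
            sources.add(lib.library_id)
    if not any(counts.values()):
        raise ValueError("marker sequence absent from every library: not usable")
    return MarkerTrace(
        marker_sequence=marker,
        per_library_counts=counts,
        source_libraries=sources,
    )


def find_markers(
    libraries_assignments: Mapping[str, Sequence[Assignment]],
    manifest: RunManifest,
    min_abundance: float = DEFAULT_MARKER_MIN_ABUNDANCE,
    max_per_library: int = 1,
) -> dict[str, list[str]]:
    """Candidate library-specific marker sequences per plant-source library.

    A candidate is a catalog-unmatched sequence whose relative abundance in
    exactly one plant-source library exceeds ``min_abundance``. Being
    unassigned guarantees it is absent from every reference catalog the
    run was classified against.
    """
    abundant: dict[str, dict[str, float]] = {}
    for lib in manifest.plant_sources():
        assignments = libraries_assignments.get(lib.library_id, ())
        total = sum(a.count for a in assignments)
        if total == 0:
            continue
        abundant[lib.library_id] = {
            a.sequence: a.count / total
            for a in assignments
            if a.category == UNASSIGNED and a.count / total > min_abundance
        }
    markers: dict[str, list[str]] = {}
    for lib_id, seqs in abundant.items():
        others = {
            s for other, m in abundant.items() if other != lib_id for s in m
        }
        specific = sorted(
            (s for s in seqs if s not in others),
            key=lambda s: (-seqs[s], s),
        )
        if specific:
            markers[lib_id] = specific[:max_per_library]
    return markers


def estimate_bleed_rate(
    marker_trace: MarkerTrace,
    library_totals: Mapping[str, int],
    manifest: Optional[RunManifest] = None,
) -> float:
    """Estimate the per-read inter-library bleed rate from a marker trace.

    Under a bleed model where each read slot of a recipient library is
    replaced by a read from foreign library *j* with probability
    ``bleed_rate x n_j / N`` (N = total reads in the multiplex group), the
    expected marker count in recipient *r* is
    ``n_r x bleed_rate x (total marker reads in sources) / N``. Each
    recipient therefore yields the unbiased estimate
    ``count_r x N / (n_r x marker_total_in_sources)``; the returned value
    averages the per-recipient estimates.
    """
    sources = marker_trace.source_libraries
    if not sources:
        raise ValueError("marker trace has no source library")
    marker_in_sources = sum(
        marker_trace.per_library_counts.get(s, 0) for s in sources
    )
    if marker_in_sources == 0:
        raise ValueError("zero marker abundance in source libraries")
    if manifest is not None:
        group = [l.library_id for l in manifest.libraries]
    else:
        group = sorted(library_totals)
    group_total = sum(library_totals[lib] for lib in group)
    recipients = [
        lib
        for lib in group
        if lib not in sources and library_totals.get(lib, 0) > 0
    ]
    if not recipients:
        raise ValueError("marker trace has no recipient library")
    estimates = [
        marker_trace.per_library_counts.get(lib, 0)
        * group_total
        / (library_totals[lib] * marker_in_sources)
        for lib in recipients
    ]
    return float(np.mean(estimates))


def diagnose_library(
    library_plant_counts: Mapping[str, int],
    diet_plant_counts: Optional[Mapping[str, int]],
    pooled_run_plant_counts: Mapping[str, int],
    breakdown: Mapping[str, float],
    diet_clades: Optional[Iterable[str]] = None,
    decision_margin: float = DEFAULT_DECISION_MARGIN,
    clade_threshold_pct: float = DEFAULT_CLADE_THRESHOLD,
) -> LibraryDiagnosis:
    """Weigh profile-similarity and clade evidence into a verdict.

    ``contamination_suspected`` when the library's plant profile resembles
    the pooled multiplexed run more than its own declared diet (by at least
    ``decision_margin``), or when a clade absent from the declared diet
    accounts for at least ``clade_threshold_pct`` of clade-assignable
    reads. ``diet_consistent`` when diet similarity dominates and the clade
    evidence matches the diet. Anything else — including a missing diet
    profile without decisive clade evidence — is ``inconclusive``.
    """
    notes: list[str] = []
    sim_diet: Optional[float] = None
    sim_pooled: Optional[float] = None

    if not library_plant_counts:
        return LibraryDiagnosis(
            library_id="",
            clade_breakdown=dict(breakdown),
            similarity_to_diet=None,
            similarity_to_pooled_run=None,
            verdict=INCONCLUSIVE,
            notes=["no plant miRNA reads"],
        )

    try:
        sim_pooled = profile_similarity(library_plant_counts, pooled_run_plant_counts)
    except ValueError as exc:
        notes.append(f"pooled similarity unavailable: {exc}")
    if diet_plant_counts is not None:
        try:
            sim_diet = profile_similarity(library_plant_counts, diet_plant_counts)
        except ValueError as exc:
            notes.append(f"diet similarity unavailable: {exc}")
    else:
        notes.append("no diet profile: verdict from clade evidence only")

    off_diet_pct = 0.0
    clade_evidence_available = bool(breakdown) and diet_clades is not None
    if clade_evidence_available:
        allowed = set(diet_clades)
        off_diet_pct = sum(
            pct
            for clade, pct in breakdown.items()
            if clade not in allowed and clade != UNRESOLVED
        )

    off_diet_hit = clade_evidence_available and off_diet_pct >= clade_threshold_pct
    similarity_hit = (
        sim_diet is not None
        and sim_pooled is not None
        and sim_pooled - sim_diet >= decision_margin
    )

    if off_diet_hit or similarity_hit:
        verdict = CONTAMINATION_SUSPECTED
        if off_diet_hit:
            notes.append(
                f"off-diet clade at {off_diet_pct:.1f}% of clade-assignable reads"
            )
        if similarity_hit:
            notes.append("plant profile resembles pooled run more than declared diet")
    elif (
        sim_diet is not None
        and sim_pooled is not None
        and sim_diet >= sim_pooled
        and (not clade_evidence_available or off_diet_pct < clade_threshold_pct)
    ):
        verdict = DIET_CONSISTENT
    else:
        verdict = INCONCLUSIVE

    return LibraryDiagnosis(
        library_id="",
        clade_breakdown=dict(breakdown),
        similarity_to_diet=sim_diet,
        similarity_to_pooled_run=sim_pooled,
        verdict=verdict,
        notes=notes,
    )


def diagnose_run(
    manifest: RunManifest,
    libraries_assignments: Mapping[str, Sequence[Assignment]],
    catalog: Catalog,
    decision_margin: float = DEFAULT_DECISION_MARGIN,
    clade_threshold_pct: float = DEFAULT_CLADE_THRESHOLD,
    marker_min_abundance: float = DEFAULT_MARKER_MIN_ABUNDANCE,
) -> ContaminationReport:
    """Full contamination diagnostics for one multiplexed run.

    Builds plant-family profiles for every library, compares each animal
    sample against its declared diet's source library and against the
    pooled plant libraries of the run, attributes clades, auto-detects
    library-specific markers, traces them, and estimates the bleed rate.
    """
    plant_profiles: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for lib in manifest.libraries:
        assignments = libraries_assignments.get(lib.library_id, ())
        totals[lib.library_id] = sum(a.count for a in assignments)
        counts: dict[str, int] = {}
        for a in assignments:
            if a.category == PLANT_MIRNA and a.family:
                counts[a.family] = counts.get(a.family, 0) + a.count
        plant_profiles[lib.library_id] = counts

    sources = manifest.plant_sources()
    pooled: dict[str, int] = {}
    for lib in sources:
        for fam, n in plant_profiles[lib.library_id].items():
            pooled[fam] = pooled.get(fam, 0) + n
    diet_profile_by_species = {
        lib.organism: plant_profiles[lib.library_id] for lib in sources
    }

    single_library_run = len(manifest.libraries) < 2

    per_library: dict[str, LibraryDiagnosis] = {}
    for lib in manifest.animal_samples():
        assignments = libraries_assignments.get(lib.library_id, ())
        breakdown = clade_breakdown(assignments, catalog)
        diet_counts = diet_profile_by_species.get(lib.diet)
        diet_clades: Optional[set[str]] = None
        if lib.diet is not None and lib.diet in catalog.species_meta:
            diet_clades = {catalog.species_meta[lib.diet][1]}
        diagnosis = diagnose_library(
            plant_profiles[lib.library_id],
            diet_counts,
            pooled,
            breakdown,
            diet_clades=diet_clades,
            decision_margin=decision_margin,
            clade_threshold_pct=clade_threshold_pct,
        )
        diagnosis.library_id = lib.library_id
        if single_library_run:
            diagnosis.verdict = INCONCLUSIVE
            diagnosis.notes.append("no co-multiplexed libraries")
        per_library[lib.library_id] = diagnosis

    traces: list[MarkerTrace] = []
    if manifest.comultiplexed and not single_library_run:
        markers = find_markers(
            libraries_assignments, manifest, min_abundance=marker_min_abundance
        )
        for lib_id in sorted(markers):
            for seq in markers[lib_id]:
                trace = trace_marker(
                    seq,
                    libraries_assignments,
                    manifest,
                    source_min_abundance=marker_min_abundance,
                )
                traces.append(trace)
        if traces:
            estimates = []
            for trace in traces:
                try:
                    estimates.append(
                        estimate_bleed_rate(trace, totals, manifest)
                    )
                except ValueError:
                    continue
            if estimates:
                bleed = float(np.mean(estimates))
                for diagnosis in per_library.values():
                    diagnosis.bleed_estimate = bleed

    return ContaminationReport(
        run_id=manifest.run_id,
        per_library=per_library,
        marker_traces=traces,
    )
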