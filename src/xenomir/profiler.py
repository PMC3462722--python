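"""Family-level library profiles and their summary statistics.

The central report row for a library gives: total miRNA-matching reads
(animal + plant), plant-matching reads, the plant/animal percentage, the
most abundant plant family, that family's share of plant reads and of
animal reads, and the family's rank within the library's animal-family
abundance ranking. Percentages use half-up decimal rounding — 3 decimals
for percentages of animal reads, 1 decimal for family shares of plant
reads — which reproduces edge cases such as 2015/2016 printing as 100.0.

The "% of animal miRNAs" denominator is animal-only reads (total minus
plant); host-genome-derived and kingdom-ambiguous multiplicities are
excluded from both kingdom totals and carried as side counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .matcher import (
    AMBIGUOUS_KINGDOM,
    ANIMAL_MIRNA,
    HOST_GENOME_DERIVED,
    PLANT_MIRNA,
    UNASSIGNED,
    Assignment,
)

DEFAULT_SIGNIFICANCE_PCT = 0.050


def _round_half_up(value: Decimal, places: int) -> float:
    q = Decimal(1).scaleb(-places)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def percent_of_animal(plant_count: int, total_mirna_reads: int) -> float:
    """Plant reads as a percent of animal-only miRNA reads, 3 decimals.

    The denominator is ``total_mirna_reads - plant_count``: the percentage
    expresses plant abundance relative to the endogenous animal miRNA
    population, not to the combined total.
    """
    animal = total_mirna_reads - plant_count
    if animal <= 0:
        raise ValueError("no animal miRNA reads: percent of animal undefined")
    if plant_count < 0:
        raise ValueError("plant count must be non-negative")
    return _round_half_up(Decimal(plant_count) * 100 / Decimal(animal), 3)


def family_share(family_count: int, plant_total: int) -> float:
    """One family's share of all plant miRNA reads, percent to 1 decimal."""
    if plant_total <= 0:
        raise ValueError("no plant miRNA reads: family share undefined")
    if not 0 <= family_count <= plant_total:
        raise ValueError("family count must lie in [0, plant_total]")
    return _round_half_up(Decimal(family_count) * 100 / Decimal(plant_total), 1)


def rank_in_animal_families(
    family_count: int, animal_family_counts: Mapping[str, int]
) -> int:
    """Competition rank of a count within the animal family abundances.

    Rank 1 + number of animal families strictly more abundant; ties share
    the smaller rank.
    """
    if not animal_family_counts:
        raise ValueError("animal family counts are empty: rank undefined")
    return 1 + sum(1 for c in animal_family_counts.values() if c > family_count)


@dataclass
class LibraryProfile:
    """Per-library family-level counts and derived summary statistics."""

    library_id: str
    total_mirna_reads: int
    plant_reads: int
    animal_reads: int
    plant_family_counts: dict[str, int]
    animal_family_counts: dict[str, int]
    host_genome_derived: int = 0
    ambiguous_kingdom: int = 0
    unassigned: int = 0
    pct_plant_of_animal: Optional[float] = None
    top_plant_family: Optional[str] = None
    top_family_reads: int = 0
    top_family_pct_of_plant: Optional[float] = None
    top_family_pct_of_animal: Optional[float] = None
    top_family_rank_in_animal: Optional[int] = None
    top_family_tie: bool = False
    rank_tie: bool = False
    flags: list[str] = field(default_factory=list)


def profile_library(
    assignments: Sequence[Assignment], library_id: str
) -> LibraryProfile:
    """Aggregate per-read assignments into a :class:`LibraryProfile`."""
    plant_counts: Counter[str] = Counter()
    animal_counts: Counter[str] = Counter()
    host_genome = ambiguous = unassigned = 0
    for a in assignments:
        if a.category == PLANT_MIRNA:
            plant_counts[a.family or "?"] += a.count
        elif a.category == ANIMAL_MIRNA:
            animal_counts[a.family or "?"] += a.count
        elif a.category == HOST_GENOME_DERIVED:
            host_genome += a.count
        elif a.category == AMBIGUOUS_KINGDOM:
            ambiguous += a.count
        elif a.category == UNASSIGNED:
            unassigned += a.count

    plant_reads = sum(plant_counts.values())
    animal_reads = sum(animal_counts.values())
    profile = LibraryProfile(
        library_id=library_id,
        total_mirna_reads=plant_reads + animal_reads,
        plant_reads=plant_reads,
        animal_reads=animal_reads,
        plant_family_counts=dict(plant_counts),
        animal_family_counts=dict(animal_counts),
        host_genome_derived=host_genome,
        ambiguous_kingdom=ambiguous,
        unassigned=unassigned,
    )
    if animal_reads > 0:
        profile.pct_plant_of_animal = percent_of_animal(
            plant_reads, profile.total_mirna_reads
        )
    else:
        profile.flags.append("no_animal_mirna_reads")

    if plant_counts:
        best = max(plant_counts.values())
        top_families = sorted(f for f, c in plant_counts.items() if c == best)
        profile.top_plant_family = top_families[0]
        profile.top_family_reads = best
        profile.top_family_tie = len(top_families) > 1
        if profile.top_family_tie:
            profile.flags.append("top_family_tie")
        profile.top_family_pct_of_plant = family_share(best, plant_reads)
        if animal_reads > 0:
            profile.top_family_pct_of_animal = percent_of_animal(
                best, best + animal_reads
            )
        if animal_counts:
            profile.top_family_rank_in_animal = rank_in_animal_families(
                best, animal_counts
            )
            profile.rank_tie = best in animal_counts.values()
            if profile.rank_tie:
                profile.flags.append("rank_tie")
    return profile


def flag_significant(
    profiles: Iterable[LibraryProfile],
    threshold_pct: float = DEFAULT_SIGNIFICANCE_PCT,
) -> list[LibraryProfile]:
    """Libraries whose plant/animal percentage reaches the threshold.

    The boundary is inclusive ("at least"); results are sorted by
    descending percentage.
    """
    hits = [
        p
        for p in profiles
        if p.pct_plant_of_animal is not None
        and p.pct_plant_of_animal >= threshold_pct
    ]
    return sorted(hits, key=lambda p: (-p.pct_plant_of_animal, p.library_id))


def profiles_to_table(profiles: Sequence[LibraryProfile]) -> pd.DataFrame:
    """Flatten profiles into the standard per-library report table."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "library_id": p.library_id,
                "total_mirna_reads": p.total_mirna_reads,
                "plant_reads": p.plant_reads,
                "animal_reads": p.animal_reads,
                "pct_plant_of_animal": p.pct_plant_of_animal,
                "top_plant_family": p.top_plant_family,
                "top_family_reads": p.top_family_reads,
                "top_family_pct_of_plant": p.top_family_pct_of_plant,
                "top_family_pct_of_animal": p.top_family_pct_of_animal,
                "top_family_rank_in_animal": p.top_family_rank_in_animal,
                "host_genome_derived": p.host_genome_derived,
                "ambiguous_kingdom": p.ambiguous_kingdom,
                "unassigned": p.unassigned,
                "flags": ";".join(p.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "library_id",
            "total_mirna_reads",
            "plant_reads",
            "animal_reads",
            "pct_plant_of_animal",
            "top_plant_family",
            "top_family_reads",
            "top_family_pct_of_plant",
            "top_family_pct_of_animal",
            "top_family_rank_in_animal",
            "host_genome_derived",
            "ambiguous_kingdom",
            "unassigned",
            "flags",
        ],
    )
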