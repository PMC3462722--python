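"""Synthetic multiplexed small-RNA runs with known ground truth.

The simulator emulates the study design that motivates the diagnostics: a
multiplexed sequencing run pooling plant source libraries (diet tissues,
plus an unrelated plant such as lettuce carrying a library-specific marker
sequence) with animal sample libraries. Each animal library is a mixture
of endogenous animal miRNAs, an optional dietary plant-miRNA spike-in
(a fraction of the animal miRNA reads, defaulting to the 0.05–0.5% band
observed in real libraries), host-genome-derived fragments, and
unclassifiable noise reads. Within a multiplex group, every library also
receives inter-library bleed: each of its read slots is replaced by a read
drawn from a foreign library with probability
``bleed_rate x (foreign library size / group size)``.

Every emitted read's true origin is recorded, so pipeline estimates of
spike fractions, clade shares and bleed rates can be checked against the
configured ground truth. The same seed always reproduces byte-identical
output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    ANIMAL,
    DICOT,
    MONOCOT,
    NOT_APPLICABLE,
    PLANT,
    Catalog,
    MiRNARecord,
    family_of,
)
from .contamination import ANIMAL_SAMPLE, PLANT_SOURCE, LibraryInfo, RunManifest
from .matcher import ReadRecord

MONOCOT_MIR168 = "UCGCUUGGUGCAGAUCGGGAC"
DICOT_MIR168 = "UCGCUUGGUGCAGGUCGGGAA"

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))

# origin labels in the ground-truth table
OWN_ANIMAL = "own-animal"
OWN_DIET = "own-diet"
OWN_PLANT = "own-plant"
GENOME = "genome"
NOISE = "noise"
MARKER = "marker"


@dataclass
class LibrarySpec:
    """Composition of one simulated library."""

    library_id: str
    organism: str
    role: str  # plant_source | animal_sample
    n_reads: int
    family_profile: dict[str, float]
    diet: Optional[str] = None
    dietary_spike: float = 0.0  # fraction of animal miRNA reads
    genome_read_fraction: float = 0.0
    unassigned_fraction: float = 0.0
    marker_abundance: float = 0.0  # plant_source only

    def __post_init__(self) -> None:
        for name in ("dietary_spike", "genome_read_fraction", "unassigned_fraction", "marker_abundance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.library_id}: {name}={v} outside [0, 1]")
        if self.genome_read_fraction + self.unassigned_fraction + self.marker_abundance > 1.0:
            raise ValueError(f"{self.library_id}: composition fractions exceed 1")
        if self.role == ANIMAL_SAMPLE and self.family_profile and not any(
            w > 0 for w in self.family_profile.values()
        ):
            raise ValueError(f"{self.library_id}: all-zero animal family profile")


@dataclass
class SimulationConfig:
    run_id: str
    seed: int
    libraries: list[LibrarySpec]
    catalog: Catalog
    bleed_rate: float = 0.0
    toy_genomes: dict[str, str] = field(default_factory=dict)
    comultiplexed: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleed_rate <= 0.05:
            raise ValueError(f"bleed_rate {self.bleed_rate} outside [0, 0.05]")


@dataclass
class SimulatedRun:
    """In-memory result of one simulated multiplexed run."""

    config: SimulationConfig
    reads_by_library: dict[str, list[ReadRecord]]
    truth: pd.DataFrame
    manifest: RunManifest
    markers: dict[str, str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write reads (collapsed FASTA), truth, manifest and catalog files."""
        from . import io as xio

        out = Path(out_dir)
        (out / "reads").mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for lib_id in sorted(self.reads_by_library):
            p = out / "reads" / f"{lib_id}.fasta"
            xio.write_reads_fasta(self.reads_by_library[lib_id], p)
            paths[f"reads/{lib_id}"] = p
        truth_path = out / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        manifest_path = out / "manifest.tsv"
        xio.write_manifest(self.manifest, manifest_path)
        paths["manifest"] = manifest_path
        catalog_path = out / "catalog.fasta"
        self.config.catalog.write_fasta(catalog_path)
        paths["catalog"] = catalog_path
        meta_path = out / "species_meta.tsv"
        xio.write_species_meta(self.config.catalog.species_meta, meta_path)
        paths["species_meta"] = meta_path
        genome_dir = out / "genomes"
        for organism in sorted(self.config.toy_genomes):
            genome_dir.mkdir(parents=True, exist_ok=True)
            p = genome_dir / f"{organism}.fasta"
            with open(p, "w") as fh:
                fh.write(f">{organism}_toy\n{self.config.toy_genomes[organism]}\n")
            paths[f"genome/{organism}"] = p
        return paths


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_RNA[rng.integers(0, 4, length)])


def make_toy_catalog(
    n_animal_families: int, n_plant_families: int, seed: int
) -> Catalog:
    """Random catalog of unique 21-nt mature sequences for simulations.

    Always contains the two clade-diagnostic miR168 variants (the monocot
    variant under rice and corn, the dicot variant under Arabidopsis and
    soybean) so that worked examples of monocot/dicot attribution run
    against any generated catalog. Additional plant families are assigned
    round-robin to corn, soybean and lettuce; animal families to three
    insect species.
    """
    if n_animal_families < 1 or n_plant_families < 1:
        raise ValueError("need at least one animal and one plant family")
    rng = np.random.default_rng(seed)
    species_meta = {
        "osa": (PLANT, MONOCOT),
        "zma": (PLANT, MONOCOT),
        "ath": (PLANT, DICOT),
        "gma": (PLANT, DICOT),
        "lsa": (PLANT, DICOT),
        "hze": (ANIMAL, NOT_APPLICABLE),
        "sfr": (ANIMAL, NOT_APPLICABLE),
        "dvv": (ANIMAL, NOT_APPLICABLE),
    }
    used = {MONOCOT_MIR168, DICOT_MIR168}

    def fresh_sequence() -> str:
        while True:
            seq = _random_rna(rng, 21)
            if seq not in used:
                used.add(seq)
                return seq

    records: list[MiRNARecord] = []

    def add(mirna_id: str, seq: str) -> None:
        code = mirna_id.split("-", 1)[0]
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

    add("osa-miR168a", MONOCOT_MIR168)
    add("zma-miR168a", MONOCOT_MIR168)
    add("ath-miR168a", DICOT_MIR168)
    add("gma-miR168", DICOT_MIR168)

    plant_species = ["zma", "gma", "lsa"]
    for i in range(n_plant_families):
        add(f"{plant_species[i % 3]}-miR{500 + i}", fresh_sequence())
    animal_species = ["hze", "sfr", "dvv"]
    for i in range(n_animal_families):
        add(f"{animal_species[i % 3]}-miR-{100 + i}", fresh_sequence())
    return Catalog(records, species_meta)


def make_toy_genome(
    length: int, planted_kmers: Sequence[str], seed: int
) -> tuple[str, list[tuple[str, int]]]:
    """Random DNA genome with given k-mers planted at recorded positions."""
    if length < 100:
        raise ValueError("toy genome length must be >= 100")
    rng = np.random.default_rng(seed)
    genome = list(_DNA[rng.integers(0, 4, length)])
    positions: list[tuple[str, int]] = []
    occupied: list[tuple[int, int]] = []
    for kmer in planted_kmers:
        kmer_dna = kmer.upper().replace("U", "T")
        if len(kmer_dna) > length:
            raise ValueError(f"planted k-mer longer than genome: {kmer!r}")
        for _ in range(1000):
            pos = int(rng.integers(0, length - len(kmer_dna) + 1))
            span = (pos, pos + len(kmer_dna))
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                occupied.append(span)
                genome[span[0] : span[1]] = list(kmer_dna)
                positions.append((kmer_dna, pos))
                break
        else:  # pragma: no cover - only with pathological packing
            raise ValueError("could not place planted k-mer without overlap")
    return "".join(genome), positions


def _zipf_profile(families: Sequence[str]) -> dict[str, float]:
    # abundance-skewed profile: a few dominant families, a long tail
    fams = sorted(families)
    weights = [1.0 / (i + 1) for i in range(len(fams))]
    total = sum(weights)
    return {f: w / total for f, w in zip(fams, weights)}


def _family_sequences(catalog: Catalog, spec_role: str, organism: str) -> dict[str, str]:
    if spec_role == PLANT_SOURCE:
        return catalog.families_of_species(organism)
    # animal endogenous profile may span all animal families
    seqs: dict[str, str] = {}
    for rec in sorted(catalog.animal_records()):
        seqs.setdefault(rec.family, rec.sequence)
    return seqs


def _sample_noise(rng: np.random.Generator, n: int) -> Counter[str]:
    out: Counter[str] = Counter()
    if n == 0:
        return out
    lengths = rng.integers(18, 31, n)
    flat = _RNA[rng.integers(0, 4, int(lengths.sum()))]
    pos = 0
    for ln in lengths:
        out["".join(flat[pos : pos + ln])] += 1
        pos += ln
    return out


def _sample_from_profile(
    rng: np.random.Generator,
    n: int,
    profile: dict[str, float],
    fam_to_seq: dict[str, str],
) -> Counter[str]:
    out: Counter[str] = Counter()
    if n == 0 or not profile:
        return out
    fams = sorted(profile)
    w = np.array([profile[f] for f in fams], dtype=float)
    w = w / w.sum()
    counts = rng.multinomial(n, w)
    for fam, c in zip(fams, counts):
        if c:
            out[fam_to_seq[fam]] += int(c)
    return out


def _sample_library_reads(
    spec: LibrarySpec,
    n: int,
    config: SimulationConfig,
    diet_profiles: dict[str, dict[str, float]],
    markers: dict[str, str],
    rng: np.random.Generator,
) -> Counter[tuple[str, str]]:
    """Draw ``n`` reads from a library's own composition: (sequence, origin) counts."""
    out: Counter[tuple[str, str]] = Counter()
    if n == 0:
        return out
    catalog = config.catalog
    if spec.role == PLANT_SOURCE:
        m, u = spec.marker_abundance, spec.unassigned_fraction
        n_plant, n_marker, n_noise = rng.multinomial(n, [1.0 - m - u, m, u])
        fam_to_seq = _family_sequences(catalog, PLANT_SOURCE, spec.organism)
        for seq, c in _sample_from_profile(rng, n_plant, spec.family_profile, fam_to_seq).items():
            out[(seq, OWN_PLANT)] += c
        if n_marker:
            out[(markers[spec.library_id], MARKER)] += int(n_marker)
        for seq, c in _sample_noise(rng, int(n_noise)).items():
            out[(seq, NOISE)] += c
        return out

    g, u, s = spec.genome_read_fraction, spec.unassigned_fraction, spec.dietary_spike
    a = (1.0 - g - u) / (1.0 + s)  # animal share; spike is s x animal share
    n_animal, n_spike, n_genome, n_noise = rng.multinomial(n, [a, s * a, g, u])
    fam_to_seq = _family_sequences(catalog, ANIMAL_SAMPLE, spec.organism)
    for seq, c in _sample_from_profile(rng, int(n_animal), spec.family_profile, fam_to_seq).items():
        out[(seq, OWN_ANIMAL)] += c
    if n_spike:
        if spec.diet is None:
            raise ValueError(f"{spec.library_id}: dietary spike without a declared diet")
        diet_seqs = catalog.families_of_species(spec.diet)
        if not diet_seqs:
            raise ValueError(
                f"{spec.library_id}: diet species {spec.diet!r} absent from catalog"
            )
        profile = diet_profiles.get(spec.diet) or _zipf_profile(list(diet_seqs))
        for seq, c in _sample_from_profile(rng, int(n_spike), profile, diet_seqs).items():
            out[(seq, OWN_DIET)] += c
    if n_genome:
        genome = config.toy_genomes.get(spec.organism)
        if genome is None:
            raise ValueError(f"{spec.library_id}: no toy genome for {spec.organism!r}")
        starts = rng.integers(0, len(genome) - 22 + 1, int(n_genome))
        for pos in starts:
            out[(genome[pos : pos + 22], GENOME)] += 1
    for seq, c in _sample_noise(rng, int(n_noise)).items():
        out[(seq, NOISE)] += c
    return out


def simulate_run(config: SimulationConfig) -> SimulatedRun:
    """Generate one multiplexed run: reads per library plus ground truth."""
    rng = np.random.default_rng(config.seed)
    catalog = config.catalog

    for spec in config.libraries:
        for fam in spec.family_profile:
            if fam not in _family_sequences(catalog, spec.role, spec.organism):
                raise ValueError(
                    f"{spec.library_id}: family {fam!r} not in catalog for "
                    f"{spec.organism!r}"
                )

    catalog_seqs = set(catalog.by_sequence)
    markers: dict[str, str] = {}
    for spec in config.libraries:
        if spec.role == PLANT_SOURCE and spec.marker_abundance > 0:
            while True:
                seq = _random_rna(rng, 24)
                if seq not in catalog_seqs and seq not in markers.values():
                    markers[spec.library_id] = seq
                    break

    diet_profiles = {
        spec.organism: spec.family_profile
        for spec in config.libraries
        if spec.role == PLANT_SOURCE
    }

    own: dict[str, Counter[tuple[str, str]]] = {}
    for spec in config.libraries:
        own[spec.library_id] = _sample_library_reads(
            spec, spec.n_reads, config, diet_profiles, markers, rng
        )

    # inter-library bleed within the multiplex group
    if config.comultiplexed and config.bleed_rate > 0 and len(config.libraries) > 1:
        group_size = sum(s.n_reads for s in config.libraries)
        for recipient in config.libraries:
            for foreign in config.libraries:
                if foreign.library_id == recipient.library_id:
                    continue
                p = config.bleed_rate * foreign.n_reads / group_size
                n_bleed = int(rng.binomial(recipient.n_reads, p))
                if n_bleed == 0:
                    continue
                contrib = _sample_library_reads(
                    foreign, n_bleed, config, diet_profiles, markers, rng
                )
                origin = f"bleed-from:{foreign.library_id}"
                for (seq, _), c in contrib.items():
                    own[recipient.library_id][(seq, origin)] += c

    reads_by_library: dict[str, list[ReadRecord]] = {}
    truth_rows = []
    for spec in config.libraries:
        reads: list[ReadRecord] = []
        for i, ((seq, origin), count) in enumerate(
            sorted(own[spec.library_id].items())
        ):
            read_id = f"r{i:06d}_x{count}"
            dna = seq.replace("U", "T")
            reads.append(ReadRecord(read_id=read_id, sequence=dna, count=count))
            truth_rows.append(
                {
                    "library_id": spec.library_id,
                    "read_id": read_id,
                    "origin": origin,
                    "sequence": dna,
                    "count": count,
                }
            )
        reads_by_library[spec.library_id] = reads

    truth = pd.DataFrame(
        truth_rows, columns=["library_id", "read_id", "origin", "sequence", "count"]
    )
    manifest = RunManifest(
        run_id=config.run_id,
        libraries=[
            LibraryInfo(
                library_id=s.library_id,
                organism=s.organism,
                role=s.role,
                diet=s.diet,
            )
            for s in config.libraries
        ],
        comultiplexed=config.comultiplexed,
    )
    return SimulatedRun(
        config=config,
        reads_by_library=reads_by_library,
        truth=truth,
        manifest=manifest,
        markers=markers,
    )


def demo_run_config(
    seed: int,
    bleed_rate: float = 0.0,
    dietary_spike: float = 0.002,
    n_reads: int = 100_000,
    n_animal_libraries: int = 3,
    n_unfed_libraries: int = 0,
    diet: str = "zma",
    genome_read_fraction: float = 0.02,
    unassigned_fraction: float = 0.02,
    marker_abundance: float = 0.2,
    n_animal_families: int = 20,
    n_plant_families: int = 24,
) -> SimulationConfig:
    """A standard simulated run: three plant sources plus animal samples.

    Plant sources are corn leaf, soybean leaf and lettuce (the lettuce
    library carries an abundant library-specific marker sequence); animal
    samples are corn earworm libraries declared as fed on ``diet``, plus
    ``n_unfed_libraries`` non-feeding neonate libraries with zero dietary
    spike (any plant reads they acquire can only come from bleed). Spike
    and bleed default to the study conditions used throughout the test
    suite (dietary spike 0.2% of animal miRNA reads; bleed off unless
    requested).
    """
    catalog = make_toy_catalog(n_animal_families, n_plant_families, seed=seed)
    genome, _ = make_toy_genome(10_000, [], seed=seed + 1)
    libraries: list[LibrarySpec] = []
    for lib_id, organism, marker in (
        ("corn_leaf", "zma", 0.0),
        ("soy_leaf", "gma", 0.0),
        ("lettuce_1", "lsa", marker_abundance),
    ):
        fams = sorted(catalog.families_of_species(organism))
        libraries.append(
            LibrarySpec(
                library_id=lib_id,
                organism=organism,
                role=PLANT_SOURCE,
                n_reads=n_reads,
                family_profile=_zipf_profile(fams),
                unassigned_fraction=unassigned_fraction,
                marker_abundance=marker,
            )
        )
    animal_fams = sorted({r.family for r in catalog.animal_records()})
    for i in range(n_animal_libraries):
        libraries.append(
            LibrarySpec(
                library_id=f"cew_{i + 1}",
                organism="hze",
                role=ANIMAL_SAMPLE,
                n_reads=n_reads,
                family_profile=_zipf_profile(animal_fams),
                diet=diet,
                dietary_spike=dietary_spike,
                genome_read_fraction=genome_read_fraction,
                unassigned_fraction=unassigned_fraction,
            )
        )
    for i in range(n_unfed_libraries):
        libraries.append(
            LibrarySpec(
                library_id=f"neonate_{i + 1}",
                organism="hze",
                role=ANIMAL_SAMPLE,
                n_reads=n_reads,
                family_profile=_zipf_profile(animal_fams),
                diet=diet,
                dietary_spike=0.0,
                genome_read_fraction=genome_read_fraction,
                unassigned_fraction=unassigned_fraction,
            )
        )
    return SimulationConfig(
        run_id=f"sim_run_{seed}",
        seed=seed,
        libraries=libraries,
        catalog=catalog,
        bleed_rate=bleed_rate,
        toy_genomes={"hze": genome},
    )
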