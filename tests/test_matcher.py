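"""Exact-match classification and the >=20-nt host-genome exclusion filter."""

import numpy as np
import pytest

from xenomir.catalog import normalize_rna, parse_mature_fasta
from xenomir.matcher import (
    AMBIGUOUS_KINGDOM,
    ANIMAL_MIRNA,
    CONTAINS,
    HOST_GENOME_DERIVED,
    PLANT_MIRNA,
    UNASSIGNED,
    GenomeKmerIndex,
    ReadRecord,
    build_sequence_index,
    classify_library,
    classify_read,
    has_genome_match,
    reverse_complement,
)
from xenomir.simulate import make_toy_genome

MONOCOT_168 = "UCGCUUGGUGCAGAUCGGGAC"


def oracle_genome_match(read_seq: str, genome: str, k: int = 20) -> bool:
    """Sliding-window brute force over both genome strands."""
    seq = read_seq.upper().replace("U", "T")
    strands = [genome.upper(), reverse_complement(genome)]
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(window in strand for strand in strands):
            return True
    return False


def oracle_classify(read_seq, catalog, genome: str | None):
    """Naive linear scan over every catalog record."""
    seq = normalize_rna(read_seq)
    matched = [r for r in catalog.records if r.sequence == seq]
    kingdoms = {r.kingdom for r in matched}
    if not matched:
        return UNASSIGNED
    if kingdoms == {"plant", "animal"}:
        return AMBIGUOUS_KINGDOM
    if kingdoms == {"animal"}:
        return ANIMAL_MIRNA
    if genome is not None and oracle_genome_match(seq, genome):
        return HOST_GENOME_DERIVED
    return PLANT_MIRNA


class TestGenomeKmerIndex:
    def test_kmers_have_length_k(self):
        idx = GenomeKmerIndex(["ACGTACGTACGTACGTACGTACGTA"], k=20)
        assert all(len(kmer) == 20 for kmer in idx.kmers)

    def test_empty_genome_gives_empty_index(self):
        assert len(GenomeKmerIndex([], k=20)) == 0

    def test_verbatim_substring_hits(self):
        genome, _ = make_toy_genome(1000, [], seed=0)
        read = genome[100:121]
        assert has_genome_match(read, GenomeKmerIndex([genome]))

    def test_reverse_complement_read_hits(self):
        genome, _ = make_toy_genome(1000, [], seed=1)
        read = reverse_complement(genome[300:321])
        assert has_genome_match(read, GenomeKmerIndex([genome]))

    def test_19nt_shared_block_does_not_hit(self):
        # genome carrying a 19-nt block of the read, but no 20-nt block
        rng = np.random.default_rng(5)
        for attempt in range(100):
            genome, _ = make_toy_genome(2000, [], seed=attempt)
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
            core = read[1:20]
            genome19 = genome[:500] + core + genome[500:]
            # retry if insertion junctions accidentally created a 20-nt match
            if not oracle_genome_match(read, genome19):
                break
        assert oracle_genome_match(core, genome19, k=19)
        assert not has_genome_match(read, GenomeKmerIndex([genome19]))

    def test_reads_shorter_than_k_never_hit(self):
        genome, _ = make_toy_genome(500, [], seed=2)
        assert not has_genome_match(genome[10:29], GenomeKmerIndex([genome]))

    def test_agrees_with_sliding_window_oracle(self):
        rng = np.random.default_rng(42)
        genome, _ = make_toy_genome(5000, [], seed=7)
        idx = GenomeKmerIndex([genome])
        for _ in range(300):
            kind = rng.integers(0, 4)
            pos = int(rng.integers(0, len(genome) - 30))
            if kind == 0:  # random read
                read = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
            elif kind == 1:  # planted substring
                read = genome[pos : pos + 21]
            elif kind == 2:  # reverse complement of a substring
                read = reverse_complement(genome[pos : pos + 24])
            else:  # substring with one mutation in the middle
                raw = list(genome[pos : pos + 21])
                raw[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[raw[10]]
                read = "".join(raw)
            assert has_genome_match(read, idx) == oracle_genome_match(read, genome)


class TestClassifyRead:
    @pytest.fixture()
    def setup(self, toy_catalog):
        genome, _ = make_toy_genome(2000, [], seed=3)
        return toy_catalog, build_sequence_index(toy_catalog), genome

    def test_dna_form_of_monocot_mir168_is_plant(self, setup):
        catalog, index, genome = setup
        read = ReadRecord("r1", MONOCOT_168.replace("U", "T"))
        a = classify_read(read, index, GenomeKmerIndex([genome]))
        assert a.category == PLANT_MIRNA
        assert a.family == "miR168"
        assert a.clades == {"monocot"}

    def test_genome_planted_read_becomes_host_derived(self, setup):
        catalog, index, _ = setup
        genome, _ = make_toy_genome(2000, [MONOCOT_168], seed=4)
        read = ReadRecord("r1", MONOCOT_168)
        a = classify_read(read, index, GenomeKmerIndex([genome]))
        assert a.category == HOST_GENOME_DERIVED

    def test_one_mismatch_is_unassigned(self, setup):
        catalog, index, genome = setup
        mutated = "A" + MONOCOT_168[1:] if MONOCOT_168[0] != "A" else "C" + MONOCOT_168[1:]
        a = classify_read(ReadRecord("r1", mutated), index, GenomeKmerIndex([genome]))
        assert a.category == UNASSIGNED

    def test_animal_reads_never_genome_screened(self, setup):
        catalog, index, _ = setup
        animal_seq = catalog.animal_records()[0].sequence
        genome, _ = make_toy_genome(2000, [animal_seq], seed=5)
        a = classify_read(ReadRecord("r1", animal_seq), index, GenomeKmerIndex([genome]))
        assert a.category == ANIMAL_MIRNA

    def test_both_kingdom_match_is_ambiguous(self, species_meta):
        seq = "ACGUACGUACGUACGUACGUA"
        cat = parse_mature_fasta(f">osa-miR9001\n{seq}\n>hsa-miR-9001\n{seq}\n", species_meta)
        a = classify_read(ReadRecord("r1", seq), build_sequence_index(cat))
        assert a.category == AMBIGUOUS_KINGDOM

    def test_empty_sequence_raises(self, setup):
        catalog, index, _ = setup
        with pytest.raises(ValueError):
            classify_read(ReadRecord("r1", ""), index)

    def test_contains_mode_accepts_flanked_mature_sequence(self, setup):
        catalog, index, genome = setup
        read = ReadRecord("r1", "AA" + MONOCOT_168 + "GG")
        strict = classify_read(read, index, match_mode="strict")
        relaxed = classify_read(read, index, match_mode=CONTAINS)
        assert strict.category == UNASSIGNED
        assert relaxed.category == PLANT_MIRNA
        assert relaxed.family == "miR168"


class TestClassifyLibrary:
    def test_empty_library(self, toy_catalog):
        assert classify_library([], build_sequence_index(toy_catalog)) == []

    def test_order_and_multiplicity_preserved(self, toy_catalog):
        index = build_sequence_index(toy_catalog)
        reads = [
            ReadRecord("a", MONOCOT_168, count=5),
            ReadRecord("b", "ACGUACGUACGUACGUACGUA", count=2),
        ]
        result = classify_library(reads, index)
        assert [a.read_id for a in result] == ["a", "b"]
        assert [a.count for a in result] == [5, 2]

    def test_category_counts_on_constructed_fixture(self, toy_catalog):
        index = build_sequence_index(toy_catalog)
        plant_seqs = sorted({r.sequence for r in toy_catalog.plant_records()})[:3]
        genome, _ = make_toy_genome(2000, [plant_seqs[0]], seed=6)
        genome_index = GenomeKmerIndex([genome])
        animal_seq = sorted({r.sequence for r in toy_catalog.animal_records()})[0]
        reads = (
            [ReadRecord(f"p{i}", s) for i, s in enumerate(plant_seqs)]
            + [ReadRecord(f"a{i}", animal_seq) for i in range(4)]
            + [ReadRecord(f"n{i}", "ACGU" * 5 + "C") for i in range(3)]
        )
        result = classify_library(reads, index, genome_index)
        by_cat = {}
        for a in result:
            by_cat[a.category] = by_cat.get(a.category, 0) + a.count
        assert by_cat == {
            PLANT_MIRNA: 2,
            HOST_GENOME_DERIVED: 1,
            ANIMAL_MIRNA: 4,
            UNASSIGNED: 3,
        }
        for a in result:  # per-read oracle agreement
            assert a.category == oracle_classify(a.sequence, toy_catalog, genome)

    def test_read_order_invariance(self, toy_catalog):
        index = build_sequence_index(toy_catalog)
        reads = [ReadRecord(f"r{i}", s) for i, s in enumerate(sorted(toy_catalog.by_sequence))]
        forward = classify_library(reads, index)
        backward = classify_library(list(reversed(reads)), index)
        assert sorted(forward, key=lambda a: a.read_id) == sorted(
            backward, key=lambda a: a.read_id
        )

    def test_oracle_equivalence_and_conservation_on_random_library(self, toy_catalog):
        rng = np.random.default_rng(123)
        index = build_sequence_index(toy_catalog)
        genome, _ = make_toy_genome(3000, [], seed=8)
        genome_index = GenomeKmerIndex([genome])
        sequences = sorted(toy_catalog.by_sequence)
        reads = []
        for i in range(600):
            kind = rng.integers(0, 3)
            if kind == 0:
                seq = sequences[rng.integers(0, len(sequences))]
            elif kind == 1:
                base = list(sequences[rng.integers(0, len(sequences))])
                base[int(rng.integers(0, len(base)))] = "ACGU"[rng.integers(0, 4)]
                seq = "".join(base)
            else:
                seq = "".join("ACGU"[j] for j in rng.integers(0, 4, 21))
            reads.append(ReadRecord(f"r{i}", seq, count=int(rng.integers(1, 10))))
        result = classify_library(reads, index, genome_index)
        assert sum(a.count for a in result) == sum(r.count for r in reads)
        for read, a in zip(reads, result):
            assert a.category == oracle_classify(read.sequence, toy_catalog, genome)

    def test_genome_growth_only_moves_plant_to_host(self, toy_catalog):
        index = build_sequence_index(toy_catalog)
        plant_seqs = sorted({r.sequence for r in toy_catalog.plant_records()})
        reads = [ReadRecord(f"r{i}", s) for i, s in enumerate(plant_seqs)]
        genome_small, _ = make_toy_genome(500, [plant_seqs[0]], seed=9)
        genome_big = genome_small + plant_seqs[1].replace("U", "T")
        small = classify_library(reads, index, GenomeKmerIndex([genome_small]))
        big = classify_library(reads, index, GenomeKmerIndex([genome_big]))
        for a_small, a_big in zip(small, big):
            if a_small.category == HOST_GENOME_DERIVED:
                assert a_big.category == HOST_GENOME_DERIVED
            if a_big.category == PLANT_MIRNA:
                assert a_small.category == PLANT_MIRNA
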