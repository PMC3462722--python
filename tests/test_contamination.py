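"""Clade attribution, profile similarity, marker tracing and verdicts."""

import numpy as np
import pytest

from xenomir.contamination import (
    CONTAMINATION_SUSPECTED,
    DIET_CONSISTENT,
    INCONCLUSIVE,
    LibraryInfo,
    RunManifest,
    clade_breakdown,
    diagnose_library,
    estimate_bleed_rate,
    find_markers,
    profile_similarity,
    trace_marker,
)
from xenomir.matcher import Assignment, build_sequence_index, classify_library
from xenomir.simulate import DICOT_MIR168, MONOCOT_MIR168, demo_run_config, simulate_run


def _assign(seq, count, category="plant_mirna", family="miR168", read_id="r"):
    return Assignment(
        read_id=read_id, sequence=seq, count=count, category=category, family=family
    )


class TestCladeBreakdown:
    def test_all_monocot_reads_give_pure_monocot(self, mir168_catalog):
        a = [_assign(MONOCOT_MIR168, 120)]
        assert clade_breakdown(a, mir168_catalog, "miR168") == {"monocot": 100.0}

    def test_96_to_4_monocot_dicot_split(self, mir168_catalog):
        a = [_assign(MONOCOT_MIR168, 96), _assign(DICOT_MIR168, 4)]
        assert clade_breakdown(a, mir168_catalog, "miR168") == {
            "dicot": 4.0,
            "monocot": 96.0,
        }

    def test_absent_family_gives_empty_map(self, mir168_catalog):
        assert clade_breakdown([_assign(MONOCOT_MIR168, 5)], mir168_catalog, "miR535") == {}

    def test_unknown_variant_counts_as_unresolved(self, mir168_catalog):
        a = [_assign(MONOCOT_MIR168, 50), _assign("A" * 21, 50)]
        out = clade_breakdown(a, mir168_catalog, "miR168")
        assert out == {"monocot": 50.0, "unresolved": 50.0}

    def test_percents_sum_to_100_when_reads_exist(self, toy_catalog):
        plant = sorted({r.sequence for r in toy_catalog.plant_records()})
        a = [_assign(s, i + 1, family=None) for i, s in enumerate(plant[:10])]
        out = clade_breakdown(a, toy_catalog)
        assert out and sum(out.values()) == pytest.approx(100.0)

    def test_host_derived_reads_excluded(self, mir168_catalog):
        a = [
            _assign(MONOCOT_MIR168, 10),
            _assign(DICOT_MIR168, 90, category="host_genome_derived"),
        ]
        assert clade_breakdown(a, mir168_catalog, "miR168") == {"monocot": 100.0}


class TestProfileSimilarity:
    def test_identical_profiles_score_one(self):
        counts = {"miR168": 100, "miR156": 40, "miR535": 7}
        assert profile_similarity(counts, counts) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        a = {"miR168": 100, "miR156": 40, "miR535": 7, "miR396": 2}
        b = {k: v**2 + 5 for k, v in a.items()}
        assert profile_similarity(a, b) == pytest.approx(1.0)

    def test_symmetry_and_key_order_invariance(self):
        rng = np.random.default_rng(3)
        a = {f"miR{i}": int(c) for i, c in enumerate(rng.integers(0, 100, 10))}
        b = {f"miR{i}": int(c) for i, c in enumerate(rng.integers(0, 100, 10))}
        b_shuffled = {k: b[k] for k in reversed(list(b))}
        assert profile_similarity(a, b) == pytest.approx(profile_similarity(b_shuffled, a))

    def test_too_few_families_raise(self):
        with pytest.raises(ValueError):
            profile_similarity({"miR168": 1}, {"miR168": 2, "miR156": 1})

    def test_null_mean_near_zero(self):
        """Two independent uniform-random profiles over 50 families are
        uncorrelated on average (Monte Carlo under the null)."""
        rng = np.random.default_rng(12345)
        scores = []
        for _ in range(1000):
            a = {f"f{i}": int(c) for i, c in enumerate(rng.integers(0, 1000, 50))}
            b = {f"f{i}": int(c) for i, c in enumerate(rng.integers(0, 1000, 50))}
            scores.append(profile_similarity(a, b))
        assert abs(float(np.mean(scores))) < 0.05


def _two_library_setup(marker_counts_animal=3):
    marker = "ACGUACGUACGUACGUACGUACGU"
    manifest = RunManifest(
        run_id="run1",
        libraries=[
            LibraryInfo("lettuce", "lsa", "plant_source"),
            LibraryInfo("insect", "hze", "animal_sample", diet="zma"),
            LibraryInfo("other_run", "hze", "animal_sample", diet="zma"),
        ],
    )
    assignments = {
        "lettuce": [
            _assign(marker, 5000, category="unassigned", family=None),
            _assign("G" * 21, 5000, family="miR500"),
        ],
        "insect": [
            _assign("U" * 22, 99_000, category="animal_mirna", family="miR-100"),
            _assign(marker, marker_counts_animal, category="unassigned", family=None),
        ],
        "other_run": [
            _assign("U" * 22, 50_000, category="animal_mirna", family="miR-100"),
        ],
    }
    return marker, manifest, assignments


class TestTraceMarker:
    def test_source_is_high_abundance_library(self):
        marker, manifest, assignments = _two_library_setup()
        trace = trace_marker(marker, assignments, manifest)
        assert trace.source_libraries == {"lettuce"}
        assert trace.per_library_counts["insect"] == 3
        assert trace.per_library_counts["other_run"] == 0

    def test_no_bleed_case(self):
        marker, manifest, assignments = _two_library_setup(marker_counts_animal=0)
        assignments["insect"] = assignments["insect"][:1]
        trace = trace_marker(marker, assignments, manifest)
        assert trace.per_library_counts["insect"] == 0

    def test_absent_marker_raises(self):
        _, manifest, assignments = _two_library_setup()
        with pytest.raises(ValueError):
            trace_marker("C" * 24, assignments, manifest)

    def test_find_markers_picks_library_specific_sequence(self):
        marker, manifest, assignments = _two_library_setup()
        found = find_markers(assignments, manifest)
        assert found == {"lettuce": [marker]}


class TestDiagnoseLibrary:
    DIET = {"miR168": 900, "miR500": 300, "miR503": 90, "miR506": 10}
    POOLED = {"miR168": 500, "miR500": 200, "miR501": 700, "miR502": 650, "miR504": 400}

    def test_off_diet_clade_triggers_contamination(self):
        # monocot-fed sample whose plant reads are overwhelmingly dicot
        d = diagnose_library(
            self.DIET, self.DIET, self.POOLED, {"dicot": 98.0, "monocot": 2.0},
            diet_clades={"monocot"},
        )
        assert d.verdict == CONTAMINATION_SUSPECTED

    def test_concordant_sample_is_diet_consistent(self):
        d = diagnose_library(
            self.DIET, self.DIET, self.POOLED, {"monocot": 100.0},
            diet_clades={"monocot"},
        )
        assert d.verdict == DIET_CONSISTENT

    def test_pooled_resemblance_triggers_contamination(self):
        library = dict(self.POOLED)
        d = diagnose_library(
            library, self.DIET, self.POOLED, {}, diet_clades={"monocot"}
        )
        assert d.verdict == CONTAMINATION_SUSPECTED

    def test_no_plant_reads_is_inconclusive(self):
        d = diagnose_library({}, self.DIET, self.POOLED, {}, diet_clades={"monocot"})
        assert d.verdict == INCONCLUSIVE
        assert "no plant miRNA reads" in d.notes

    def test_missing_diet_profile_uses_clade_evidence_flagged(self):
        d = diagnose_library(
            self.DIET, None, self.POOLED, {"dicot": 90.0, "monocot": 10.0},
            diet_clades={"monocot"},
        )
        assert d.verdict == CONTAMINATION_SUSPECTED
        assert any("clade evidence only" in n for n in d.notes)


class TestEstimateBleedRate:
    def _simulated_trace(self, seed, bleed, source_min_abundance=1e-4):
        sim = simulate_run(
            demo_run_config(seed, bleed_rate=bleed, dietary_spike=0.0, n_reads=100_000)
        )
        index = build_sequence_index(sim.config.catalog)
        assignments = {
            lib: classify_library(reads, index)
            for lib, reads in sim.reads_by_library.items()
        }
        totals = {lib: sum(a.count for a in assignments[lib]) for lib in assignments}
        marker = sim.markers["lettuce_1"]
        trace = trace_marker(
            marker, assignments, sim.manifest, source_min_abundance=source_min_abundance
        )
        return trace, totals, sim.manifest

    def test_recovers_configured_bleed_within_sampling_error(self):
        bleed = 1e-3
        trace, totals, manifest = self._simulated_trace(seed=4, bleed=bleed)
        estimate = estimate_bleed_rate(trace, totals, manifest)
        marker_total = sum(
            trace.per_library_counts[s] for s in trace.source_libraries
        )
        expected_counts = bleed * marker_total / sum(totals.values()) * 100_000
        n_recipients = len(totals) - len(trace.source_libraries)
        se = np.sqrt(expected_counts * n_recipients) / n_recipients / expected_counts * bleed
        assert abs(estimate - bleed) <= 3 * se

    def test_zero_bleed_gives_zero_estimate(self):
        trace, totals, manifest = self._simulated_trace(seed=5, bleed=0.0)
        assert estimate_bleed_rate(trace, totals, manifest) == 0.0

    def test_recipients_with_identical_bleed_agree(self):
        # stricter source threshold: at this bleed level the recipients'
        # marker abundance itself exceeds the default
        trace, totals, manifest = self._simulated_trace(
            seed=6, bleed=5e-3, source_min_abundance=1e-2
        )
        marker_total = sum(trace.per_library_counts[s] for s in trace.source_libraries)
        group_total = sum(totals.values())
        per_recipient = [
            trace.per_library_counts[lib] * group_total / (totals[lib] * marker_total)
            for lib in totals
            if lib not in trace.source_libraries
        ]
        expected = 5e-3 * marker_total / group_total * 100_000
        spread = 3 * np.sqrt(expected) / expected * 5e-3
        assert max(per_recipient) - min(per_recipient) <= 2 * spread

    def test_zero_marker_abundance_in_source_raises(self):
        trace, totals, manifest = self._simulated_trace(seed=7, bleed=0.0)
        trace.per_library_counts = {lib: 0 for lib in trace.per_library_counts}
        trace.source_libraries = {"lettuce_1"}
        with pytest.raises(ValueError):
            estimate_bleed_rate(trace, totals, manifest)


class TestVerdictProperties:
    def _verdicts(self, seed, bleed, spike):
        from xenomir.contamination import diagnose_run

        sim = simulate_run(
            demo_run_config(seed, bleed_rate=bleed, dietary_spike=spike, n_reads=50_000)
        )
        index = build_sequence_index(sim.config.catalog)
        assignments = {
            lib: classify_library(reads, index)
            for lib, reads in sim.reads_by_library.items()
        }
        report = diagnose_run(sim.manifest, assignments, sim.config.catalog)
        return {lib: d.verdict for lib, d in report.per_library.items()}

    def test_bleed_only_flags_contamination(self):
        hits = 0
        total = 0
        for seed in range(1, 6):
            for verdict in self._verdicts(seed, bleed=1e-3, spike=0.0).values():
                total += 1
                hits += verdict == CONTAMINATION_SUSPECTED
        assert hits / total >= 0.9

    def test_spike_only_is_diet_consistent(self):
        hits = 0
        total = 0
        for seed in range(1, 6):
            for verdict in self._verdicts(seed, bleed=0.0, spike=0.002).values():
                total += 1
                hits += verdict == DIET_CONSISTENT
        assert hits / total >= 0.9

    def test_increasing_bleed_never_rescinds_contamination(self):
        for seed in (1, 2, 3):
            flagged = False
            for bleed in (0.0, 1e-4, 1e-3, 1e-2):
                verdicts = self._verdicts(seed, bleed=bleed, spike=0.0)
                now_flagged = any(
                    v == CONTAMINATION_SUSPECTED for v in verdicts.values()
                )
                if flagged:
                    assert now_flagged
                flagged = flagged or now_flagged
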