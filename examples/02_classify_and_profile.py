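"""Read classification and per-library abundance statistics.

Recomputes the percent columns of the packaged 19-library published
summary table from its raw counts, then simulates a small corn-fed animal
library with a 0.2% dietary plant-miRNA spike-in, classifies every read by
exact full-length identity, and prints the same statistics for it. The
plant/animal percentage uses animal-only reads as denominator.
"""

from xenomir import build_sequence_index, classify_library, profile_library
from xenomir.datasets import public_library_table
from xenomir.profiler import family_share, percent_of_animal
from xenomir.simulate import demo_run_config, simulate_run

table = public_library_table()
print("published libraries, percent columns recomputed from counts:")
print(f"{'library':>10} {'total':>9} {'plant':>6} {'%plant/animal':>13} {'top family':>10} {'%of plant':>9}")
for row in table.head(4).itertuples(index=False):
    pct = percent_of_animal(row.plant_reads, row.total_mirna_reads)
    share = family_share(row.top_family_reads, row.plant_reads)
    print(f"{row.library_id:>10} {row.total_mirna_reads:>9} {row.plant_reads:>6} "
          f"{pct:>13.3f} {row.top_plant_family:>10} {share:>9.1f}")

print("\nsimulated corn-fed library (dietary spike 0.2% of animal miRNA reads):")
sim = simulate_run(demo_run_config(seed=1, dietary_spike=0.002, n_reads=100_000))
index = build_sequence_index(sim.config.catalog)
assignments = classify_library(sim.reads_by_library["cew_1"], index)
profile = profile_library(assignments, "cew_1")
print(f"  total miRNA reads : {profile.total_mirna_reads}")
print(f"  plant miRNA reads : {profile.plant_reads}")
print(f"  % of animal miRNAs: {profile.pct_plant_of_animal:.3f}  (configured 0.200)")
print(f"  top plant family  : {profile.top_plant_family} "
      f"({profile.top_family_reads} reads, {profile.top_family_pct_of_plant:.1f}% of plant)")
print(f"  rank in animal families: {profile.top_family_rank_in_animal}")
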