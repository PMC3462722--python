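# xenomir

Detection and contamination diagnostics for plant miRNAs in animal
small-RNA sequencing libraries.

## The problem

Plant microRNAs are routinely detected at low levels in animal small-RNA
(sRNA) sequencing datasets — most conspicuously miR168 — and it is
contested whether they reflect genuine dietary uptake into animal tissues
or artifacts of the sequencing process itself. `xenomir` is a pipeline for
making that call rigorously. It is aimed at bioinformaticians auditing
sRNA datasets (their own, or public archives) for cross-kingdom reads and
deciding whether those reads are biology or contamination.

The pipeline implements:

1. **Exact-match classification.** A read counts as a miRNA hit only on a
   perfect match over the entire length of a mature sequence from a
   kingdom-annotated catalog (miRBase-style FASTA plus a species→kingdom/
   clade table). Reads matching plant mature sequences are then screened
   against the host genome: any read sharing a contiguous exact match of
   ≥ 20 nt with either genome strand is reclassified as host-genome
   derived and excluded from the plant count.
2. **Library profiling.** For each library: total miRNA reads, plant
   reads, the plant/animal percentage
   `100 · n_plant / (n_total − n_plant)` (animal-only denominator,
   half-up rounding to 3 decimals), the most abundant plant family, its
   share of plant reads, and its competition rank among the library's
   animal miRNA families. Libraries where plant reads reach ≥ 0.050% of
   animal miRNA reads are flagged as significant.
3. **Clade-of-origin attribution.** The monocot and dicot miR168 variants
   differ at exactly two nucleotides, so an exact match resolves each read
   to one flowering-plant clade; per-library monocot/dicot breakdowns
   reveal, e.g., monocot-variant reads in a dicot-fed animal.
4. **Multiplexed-run contamination diagnostics.** Spearman rank
   correlation (on log1p counts over the union of plant families)
   compares each animal library's plant-miRNA profile with its declared
   diet and with the pooled co-multiplexed plant libraries;
   library-specific marker sequences are traced across the run and
   inverted into a per-run bleed-rate estimate; the evidence is combined
   into a per-library verdict (`diet_consistent`,
   `contamination_suspected`, `inconclusive`).
5. **A ground-truth simulator** for multiplexed runs (animal miRNA
   background, dietary spike-ins at the 0.05–0.5% band seen in real
   libraries, host-genome reads, noise, and inter-library bleed), so every
   stage is testable without downloads.

## Worked example

`examples/` contains one narrative script per capability. Abridged output
of `python examples/03_contamination_diagnostics.py`, which simulates a
multiplexed run (corn, soybean and lettuce libraries pooled with three
corn-fed insect libraries) where the insects' only plant reads come from
inter-library bleed at rate 10⁻³:

```
marker sequence (lettuce-specific): CGUUAAUUACUCCUCCGGAAUUUG
  source libraries: ['lettuce_1']
       cew_1:      5 marker reads
   lettuce_1:  20006 marker reads
...
configured bleed rate: 0.001
cew_3: verdict=contamination_suspected  sim(diet)=0.19 sim(pooled run)=0.77
       clades monocot/dicot = 33%/67%  bleed estimate = 9.00e-04
```

Each line reads: the lettuce-private marker leaked a handful of reads into
every co-multiplexed library; the insect library's plant profile
correlates with the pooled run (0.77) far better than with its declared
corn diet (0.19); two-thirds of its clade-assignable plant reads are
dicot although corn is a monocot; and inverting the marker trace recovers
the configured bleed rate (9.0·10⁻⁴ vs 10⁻³). Verdict: contamination.

`examples/02_classify_and_profile.py` shows the abundance statistics on
both published library counts and a simulated dietary spike-in:

```
   library     total  plant %plant/animal top family %of plant
 SRR039190   1175650   5342         0.456     miR168      53.5
...
simulated corn-fed library (dietary spike 0.2% of animal miRNA reads):
  % of animal miRNAs: 0.188  (configured 0.200)
```

## Command-line interface

The same stages are available as a thin CLI for file-based runs:

```sh
xenomir simulate --out run1 --seed 7
xenomir run --config pipeline.yaml --out results/
xenomir classify --config pipeline.yaml   # stages compose identically
```

The pipeline config is a small YAML file naming the catalog FASTA, species
metadata TSV, run manifest TSV, read files (FASTA with `_xN` collapsed
counts, or FASTQ), and optional per-organism genome FASTAs; thresholds
(significance percent, decision margin, clade threshold, marker abundance)
are all overridable. Outputs are flat TSV/JSON reports with a versioned
schema header and a config-hash/seed provenance stamp, plus a
machine-readable run log with per-stage read-count conservation checks.

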