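# Methods

This note documents the models, conventions and numerical choices behind
`xenomir`, in the order the pipeline applies them.

## Classification model

A read is a miRNA hit if and only if its (adapter-trimmed, T→U
normalized) sequence is exactly equal to a catalog mature sequence — same
length, zero mismatches. This is the strictest reading of "perfect match
over the entire length", and the only one under which read-level counting
is unambiguous. A `contains` match mode is available for libraries with
untrimmed flanking bases: it additionally accepts reads that carry a full
mature sequence as a substring. Strict mode is the default and is what
every reported statistic uses.

Kingdom assignment follows from the matched records. A read matching both
a plant and an animal mature sequence is categorized `ambiguous_kingdom`,
excluded from both kingdom totals, and surfaced separately: the
intra-catalog query `cross_kingdom_identical` exists precisely to show
that for real catalogs this set is empty, so any occurrence deserves
attention rather than a silent tie-break. When matched records of the
deciding kingdom span several families (possible when species share a
mature sequence across families), the lexicographically smallest family
key is reported.

### Host-genome exclusion

Plant-matching reads are screened against the consuming organism's
genome; a read sharing a contiguous exact block of ≥ 20 nt with either
strand is recategorized `host_genome_derived` and excluded from the plant
count. The filter is implemented as a set of all 20-mers of both genome
strands: a shared block of length ≥ 20 exists iff some 20-nt window of
the read is in the set, so k-mer membership is exact, not heuristic.
Reads shorter than 20 nt cannot satisfy the criterion and pass. Both
strands are indexed because genomic provenance is strand-agnostic. Only
plant-matching reads are screened; animal-matching reads never are. Only
contiguous exact matches count — no spliced or near matches.

### Family normalization

Catalog identifiers follow the `<species>-<name>` grammar. The family key
is the name with a single trailing lowercase variant letter and any
trailing `-<n>` locus suffix removed; arm suffixes `-3p`/`-5p` are
retained, because the two arms are distinct mature products (`zma-miR168a
→ miR168`, `dme-miR-8-5p → miR-8-5p`). The species prefix is stripped
only when what follows looks like a family name, which makes the function
idempotent on family keys — including dashed keys like `miR-8-5p` and
`let-7`. Plant-style (`miR168`) and animal-style (`miR-279`) spellings
are deliberately not unified: the kingdom partition makes cross-style
unification unnecessary, and preserving them verbatim keeps keys
traceable to their catalog entries.

## Profile statistics

For a library with `n_total` miRNA-matching reads of which `n_plant`
match plant records:

* `% of animal miRNAs` = `100 · n_plant / (n_total − n_plant)` — the
  denominator is animal-only reads. Rounded half-up to 3 decimals.
* A family's `% of plant miRNAs` = `100 · n_family / n_plant`, rounded
  half-up to 1 decimal. Half-up rounding is load-bearing: a library with
  2015 of 2016 plant reads in one family prints 100.0, matching published
  convention.
* Rank within animal families is competition ranking (1 + number of
  animal families strictly more abundant; ties share the smaller rank,
  and ties are flagged in the output).
* Top-family ties resolve to the lexicographically smallest key, flagged.
* Host-genome-derived and kingdom-ambiguous multiplicities are excluded
  from both kingdom totals and carried as side counts, so
  `n_total = n_plant + n_animal` always holds.

The significance threshold — plant reads ≥ 0.050% of animal miRNA reads,
boundary inclusive — is a configurable default, not hard-coded.

## Contamination diagnostics

Three independent evidence streams are combined per animal library:

**Clade breakdown.** Each matched plant sequence variant inherits the
clade set of the plant records carrying it. Variants carried by exactly
one clade are diagnostic; variants carried by both clades (or none) are
reported as `unresolved` and never split fractionally — splitting would
require priors the data does not supply. Percentages are over
clade-assignable reads and sum to 100 whenever any exist.

**Profile similarity.** Spearman rank correlation over the union of plant
family keys (absent families count 0), computed on log1p-transformed
counts. Rank correlation is invariant to library size and any monotone
transform of counts, which is exactly the robustness wanted when
comparing libraries sequenced at very different depths; log1p makes the
inputs well-defined at zero. Fewer than 3 families in the union is an
error (the statistic is unstable); a constant profile has no ranks, and
the score is defined as 1.0 against an identical profile and 0.0
otherwise.

**Marker tracing.** A library-specific marker is a catalog-unmatched
sequence whose relative abundance exceeds 10⁻⁴ in exactly one
plant-source library of the run (being unassigned guarantees absence from
every reference catalog in play). Its exact-match counts across all
libraries form the trace; nonzero counts in co-multiplexed libraries are
direct evidence of bleed, and zero counts in libraries from other runs
are the matching negative control.

### Verdict rule

`contamination_suspected` when similarity-to-pooled-run exceeds
similarity-to-diet by ≥ 0.2 (decision margin), OR a clade absent from the
declared diet accounts for ≥ 50% of clade-assignable reads — the latter
mirrors the evidential standard of finding >96% monocot-variant reads in
dicot-fed animals. `diet_consistent` when diet similarity is at least the
pooled similarity and no off-diet clade crosses the threshold. Everything
else — no plant reads, too few families for a stable correlation, missing
diet profile without decisive clade evidence, a single-library run — is
`inconclusive`, with an explanatory note. Both thresholds are
configurable. A missing diet profile downgrades to clade-only evidence
and is flagged.

### Bleed-rate estimate

Under the bleed model below, the expected marker count in recipient *r*
is `n_r · β · M / N`, where `β` is the per-slot bleed rate, `M` the total
marker reads in the source libraries and `N` the total reads of the
multiplex group. Each recipient therefore yields the unbiased estimate
`count_r · N / (n_r · M)`; the report averages recipients. Note the
naive normalization `count_r / (n_r · p_source)` (marker abundance only)
would recover `β` scaled by the source's share of the group, not `β`
itself; the `N/M` form inverts the generative model exactly, and
simulation confirms it is unbiased (mean 9.9·10⁻⁴ ± 0.4·10⁻⁴ at
configured 10⁻³ over 40 runs).

## Simulator

Each library is a multinomial mixture. Animal samples: endogenous animal
miRNAs (abundance-skewed 1/rank family profile), a dietary spike drawn
from the diet plant's family profile at a configured fraction *s* of the
animal miRNA reads (the animal share is scaled by 1/(1+s) so the expected
plant/animal ratio is exactly *s*), host-genome fragments (22-nt windows
of a random toy genome), and noise reads (uniform random, 18–30 nt).
Plant sources: the species' plant families, an optional library-private
marker sequence, and noise. miRNA reads are emitted at exact mature
length, compatible with strict matching.

Bleed is modeled as uniform per-read contamination proportional to
co-multiplexed library sizes: each read slot of a recipient receives a
read drawn from foreign library *j*'s own composition with probability
`β · n_j / N`. No index-swap asymmetry is modeled — this is the simplest
mechanism that reproduces the observable signatures (pooled-run profile
resemblance, marker leakage, mixed clades in animal libraries).

Default conditions are fixed to the study setting: dietary spikes in the
0.05–0.5% band observed in real libraries (0.2% in the standard
scenario), bleed 10⁻³ for contamination scenarios, 10⁵ reads per library
for recovery experiments, three plant sources (corn, soybean, lettuce
with a marker at 20% relative abundance) pooled with corn-fed and
optionally non-feeding animal libraries. A given seed reproduces
byte-identical output.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: sequencing errors and quality variation,
adapter remnants, length heterogeneity of real mature miRNAs beyond the
noise class, isomiR variation, index-hopping asymmetries between barcode
pairs, and the compositional complexity of real transcriptomes. The
simulator establishes that the *inference machinery* is correct under its
generative model, not that real libraries satisfy that model.

## Numerical and degenerate-input conventions

* Percent rounding: decimal half-up (not banker's), 3 decimals for
  percentages of animal reads, 1 for family shares.
* `% of animal` is undefined when a library has no animal miRNA reads
  (plant sources): reported as missing with a flag, not as infinity.
* Family share is an error at zero plant reads; callers report "no plant
  miRNAs" instead.
* Empty read sequences are errors; reads shorter than the genome k never
  pass the genome filter; an empty catalog FASTA yields an empty catalog.
* Classification is order-independent and deterministic; profiles are
  invariant under permutation of assignments.
* Unknown species codes in a catalog are load-time errors, so kingdom and
  clade annotation is always complete.

## Problem sizes

The test suite and the acceptance script use catalogs of ~100 records,
10-kb toy genomes, libraries of 10³–10⁵ reads and 10-seed simulation
batches. These sizes give the recovery experiments tight binomial
standard errors (3 SE ≈ 0.04% on a 0.2% spike at 10⁵ reads) while the
whole suite runs in well under a minute; the exact-match and k-mer
machinery scales linearly for full-size catalogs and genomes.

## Known limitations

* Only exact identity is implemented for the cross-kingdom and
  marker-specificity checks; near-matches are out of scope.
* The genome filter considers contiguous exact matches only.
* The published "%plant/all" per-run-library column of the insect feeding
  experiment is reported as data but not recomputed: its printed values
  cannot be reconciled with any denominator printed alongside them.
* Verdicts are heuristics with configurable thresholds, designed to be
  conservative (surface ambiguity as `inconclusive` rather than guess).
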