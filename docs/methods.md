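# Methods

## The synthetic diploid genome

All validation rests on a generator whose output statistically mimics a
compact, heterozygous, LTR-purging plant genome while recording exact ground
truth. Stages (all deterministic given `SimulationConfig.seed`; independent
substreams per stage, so changing one stage's parameters does not perturb the
randomness of another):

1. **Ancestral haploid genome.** Each contig (default 2 × 1 Mb) alternates
   gene islands with repeat-dense blocks. Genes are random-codon CDS (ATG …
   sense codons … TAA; 150–650 codons) separated by ~1.1 kb intergenic gaps;
   gene count is `contig_length × gene_density` with a default of one gene
   per 4.0 kb. Repeat blocks absorb the remaining sequence budget and are the
   only places elements are planted, giving the gene-rich / repeat-dense
   mosaic seen in compact genomes.
2. **LTR element planting.** A two-family library (Gypsy-like: 3.5 kb LTR +
   4 kb internal; Copia-like: 1 kb LTR + 1.5 kb internal; `TG…CA` termini)
   with a 33:1 Gypsy:Copia sampling weight, matching the strongly
   Gypsy-skewed intact populations of such genomes. Each copy is inserted
   with a 5 bp target-site duplication. For a planted age T, each LTR of the
   copy is mutated independently with per-base substitution probability μT
   (substitutions only, no indels, so identity-based dating is exact in
   expectation at 2μT and the Jukes–Cantor model is isolated as the object
   under test). Ages are drawn from a truncated exponential (mean 0.4 My,
   max 2 My) — the young-skewed profile of an active, rapidly purged
   population. μT ≥ 0.75 is refused (unrecoverable divergence).
3. **Solo-LTR formation.** For a `solo_fraction` subset (default 0.8,
   giving a planted solo:intact ratio of 4), the internal region plus one
   LTR is deleted — the unequal-homologous-recombination footprint — leaving
   a single LTR flanked by the original TSD.
4. **Haplotype derivation.** Haplotype B = haplotype A plus (i) random
   substitutions at 0.018/bp (98.2% identity), sparing the dated LTR spans so
   planted divergence stays exactly μT per copy, and (ii) `n_planted_indels`
   (default 20) haplotype-specific segments of 4.8–85 kb (log-uniform),
   inserted into one haplotype chosen uniformly. Each segment is assembled
   from intact elements (counts chosen to best hit the 58% LTR-bp target
   given element-size granularity), genes (~9% of bp) and random filler;
   segment elements draw younger ages (exponential, mean 0.04 My, max
   0.1 My), planting the young-LTR enrichment the statistics stage must
   detect. Breakpoints are placed ≥ 300 bp from genes and ≥ 800 bp from
   planted repeats so that the flanking sequence is unique — an
   identifiability condition for any anchor-based caller, not a convenience:
   an indel whose breakpoint lies inside a repeat copy is ambiguous even in
   principle.
5. **Methylome.** Every cytosine on both strands of haplotype A (profiling
   the second haplotype would duplicate each signal without testing anything
   new) gets a context by the trinucleotide rule and a true level by
   compartment: gene bodies ≈ 0.01 in all contexts (no gene-body
   methylation), LTR bodies 0.85/0.75/0.10 (CpG/CHG/CHH), background
   0.05/0.04/0.02, with linear ramps across 1 kb flanks of LTR spans.
   Coverage is Poisson (default 10×), methylated counts Binomial per
   replicate (default 3).
6. **Expression.** Indel-region genes draw from a silent/expressed mixture
   so that 74% fall below TPM 0.5 in expectation; the remaining genes are
   log-normal and absorb the normalization so one sample's TPM column sums
   to exactly 10⁶ (one sample suffices — the downstream consumer is a
   threshold count, not a differential analysis).

What the fixture does **not** emulate: sequencing reads and their error
models, assembly artifacts (collapsed or chimeric haplotypes), nested TE
insertions, non-LTR repeats, tandem arrays beyond what random placement
produces, CG/CHG symmetry of real methylomes, and biological covariation of
expression with methylation. Passing tests therefore demonstrate the
*operations* are correct under clean, known conditions — not that real
assemblies meet those conditions.

## Alignment primitives

All pairwise alignment routes through edlib (global, unit-cost optimal edit
distance) with the extended CIGAR tallied into match/mismatch/gap columns.
Identity = matches / all columns; LTR divergence p = mismatches / non-gap
columns (gap handling must be pinned down somewhere: excluding gap columns
makes p a pure substitution estimate). The internal alignment score is
match +1, mismatch −1, gap column −2. Because a parsimony aligner
occasionally substitutes a gap pair for runs of mismatches, p is very
slightly deflated at high divergence; on the fixture this appears as an age
regression slope of ~0.94–0.97 (within the 1.0 ± 0.1 recovery band) rather
than 1.0.

## Synteny

Candidate duplicated pairs share at least one exact 21-mer between CDS;
pairs with global identity ≥ 0.90 are kept (well below the ~98% CDS identity
that 1.8% substitution divergence produces, and far above chance for
random-codon CDS), at most 5 partners per gene. Tandem hits within 5 ranks
on the same contig collapse to the best-scoring representative before
chaining. Chaining is an O(n²) DP for the maximum-anchor chain with strictly
monotone ranks on both contigs (increasing or decreasing ⇒ orientation) and
rank gaps ≤ 10, extracted greedily best-first (ties: higher score, then
earlier rank) with used anchors removed; chains need ≥ 5 anchors. Candidate
haplotype pairs require both spans ≥ 75 kb (scaled to 50 kb in the worked
example where contigs are ~1.5 Mb). Reciprocal-best filtering is not
applied by default; the identity threshold and chaining already suppress
paralogous chains on the fixture.

## Haplotype indel calling

Anchors are maximal exact matches built from k-mers (k = 21) unique in both
sequences, merged along diagonals, kept at ≥ 100 bp, and chained by a
length-weighted LIS on both coordinates. Long exact anchors are sparse under
1.8% substitution noise (mean identical run ≈ 55 bp), so each inter-anchor
gap is then re-anchored locally at ≥ 25 bp (= min_anchor/4); within a gap
the two subsequences are already homologous by the flanking chain, so short
local matches are trustworthy there while remaining excluded globally.

A gap is called an indel when it is ≥ 4 kb on one sequence and ≤ 500 bp on
the partner — the testable operationalization of "haplotype-specific"
(replacing manual curation); symmetric large gaps are reported as divergent
regions, not indels. 4 kb sits just below the smallest indel the analysis is
designed around (4.8 kb) to avoid censoring at the boundary. Breakpoints are
refined by splitting the partner gap between the carrier gap's two ends at
the offset maximizing summed prefix+suffix base agreement (substitution-
tolerant, vectorized); on the fixture this pins breakpoints to ≤ 3 bp.

Content classification counts annotated bp within the call span; bases under
both gene and LTR annotations count to LTR (repeat priority). Features
belong to a span at ≥ 50% length overlap. Flanks are matched-width by
default, truncated flanks computed on available bases and flagged.

## LTR dating and solo LTRs

p from the 5′/3′ LTR global alignment; K = −(3/4)·ln(1 − (4/3)p); T = K/2μ
with μ = 1.3 × 10⁻⁸ bp⁻¹ yr⁻¹. p ≥ 0.75 ⇒ the element is flagged undatable,
kept in counts, excluded from age means. Age-recovery precision is
binomially limited: SE(T)/T ≈ 1/√(2μT·L) for LTR length L, hence ~10%
relative error at T = 1 My needs L in the few-kb range — one reason the
fixture's dominant family carries a 3.5 kb LTR.

Solo candidates come from scanning the genome with the family library (LTR
*and* internal entries — internal hits are what disqualify an intact
element's LTRs from being "solo"). Seeding is exact 21-mer matching via
integer k-mer encoding; seed clusters (gap ≤ 300 bp) are scored by global
alignment of the covered ranges, with library coverage estimated from the
covered entry range. The four acceptance rules are a pure conjunction:
isolation (no other LTR-related span within 300 bp), coverage ≥ 0.80,
score > 300, length ≥ 100 bp. The score threshold keeps its published
numeric value but lives on the internal +1/−1/−2 scale; with ≥ 1 kb LTRs and
≤ 5% divergence genuine solos score far above it while sub-300 bp or
low-identity hits cannot reach it. The solo:intact aggregate is
Σsolo/Σintact over families whose mean intact-LTR length falls in the
central 95% interval of intact LTR lengths (total-count ratio rather than a
mean of per-family ratios — robust to tiny families; the per-family table
preserves the alternative; an "≤ 95th percentile" window is selectable).
Families with no intact elements report an undefined (not zero) ratio and
are excluded from the aggregate.

## Methylation profiling

Site level = m/(m+u) for sites with total ≥ 3 reads (the coverage filter);
replicate averaging is the per-site mean over replicates where the site
survived, keeping sites present in ≥ 1 replicate. Metagene profiles pool
sites across features with equal per-site weight (not per-feature
averaging); bodies are length-normalized into 20 bins, flanks binned at
50 bp over 1 kb, minus-strand features flipped; features shorter than the
bin count contribute body sites to the central bin and are flagged.
Symmetric CpG sites are not merged across strands. Window tracks report
per-50 kb context means and gene/LTR bp densities with the Pearson
correlation of LTR density and CpG level.

Recovery testing compares each observed bin mean to the mean *planted* level
of the same sites, with a simultaneous 99% binomial band: with ~360 bins a
per-bin 99% interval would be expected to fail a few bins by construction,
so the band uses the Bonferroni quantile z₁₋₀.₀₁/(2·nbins) (and an absolute
floor of 0.01 where the sampling error is tiny).

## Statistics

The rank-sum test uses mid-ranks. For pooled n ≤ 20 the null is enumerated
exactly over all C(N, n_x) assignments — valid under ties, unlike classical
no-tie exact tables, which is why the enumeration is implemented here rather
than delegated; the two-sided p is P(|W − E W| ≥ |w − E W|). Larger samples
use the normal approximation with tie-corrected variance and 0.5 continuity
correction; a seeded ≥ 10⁴-resample permutation fallback is selectable.
Degenerate input (all values identical) returns p = 1 with a warning.
Two-sided p-values are the default throughout; no multiple-testing
correction is applied (single planned tests), and the report states each
test's sample sizes.

Young-LTR enrichment partitions dated elements by ≥ 50% overlap with called
indel spans, reports young proportions (cutoff 0.1 My) and the rank-sum on
insertion times. Composition aggregates are bp-weighted means. Display
rounding: densities/percentages 1 decimal, ratios 2 decimals, ages 2
significant figures in My.

## Problem sizes

The default study conditions are 2 × 1 Mb contigs, 150 planted elements
(80% solo), 20 indels, 10× methylome × 3 replicates; dedicated runs use 100
uniform-age elements for dating recovery and an indel-free genome for the
solo:intact ratio. These sizes make every property measurable (≥ 100
elements for regression, ≥ 10³ sites per metagene bin) while a full
simulation-plus-analysis cycle stays around a minute.

## Known limitations

- Dating assumes substitution-only LTR divergence; real elements accumulate
  indels and gene conversion between LTRs, biasing T downward.
- The caller reports clean insertions only; balanced or nested variation
  surfaces as "divergent regions" and is not classified further.
- The solo scanner's coverage estimate derives from seed extents; heavily
  diverged (> ~15%) solos would be under-covered and missed, a regime the
  fixture does not enter.
- Synteny assumes single-copy genes after tandem collapsing; large gene
  families could still chain paralogous blocks on real data.
- The enrichment test treats elements as independent; clustered insertions
  violate this mildly.
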