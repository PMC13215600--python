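# Methods

This note documents the models, defaults and numerical choices behind
`crypticex`, what the synthetic data does and does not emulate, and the
known limitations.

## Coordinate conventions

All in-memory intervals are 0-based half-open on the plus strand of the
contig; VCF/GFF3 (1-based inclusive) and BED12 (0-based half-open)
conversions happen only in `crypticex.io`. Strand-sensitive quantities
(HGVS offsets, "the eighth base of the cryptic exon", consensus
orientation) are always computed on the coding strand, so minus-strand loci
give identical answers; the generator builds every locus on the coding
strand and mirrors it, and the test suite runs strand-sensitive stages on
both orientations.

## The synthetic locus

`LocusSpec` defaults encode the study geometry rather than arbitrary
round numbers: five exons (100/127/120/100/150 bp), CDS starting 50 bp into
exon 1 so that exon 2 ends at coding position c.177; a 4,000 bp intron 2
carrying a 92 bp cryptic exon whose first base lies 1,770 bp into the
intron, so the planted G>C at the exon's eighth base sits at c.177+1778; an
AG…GT splice context on the coding strand (the canonical dinucleotides —
the real acceptor/donor sequences are not published); a TGA planted exactly
24 codons after the cryptic exon's first codon; and a 143 bp extended
acceptor on exon 3 used by the second case-only isoform. With the published
RT-PCR primer pair planted in exons 2 and 5, the trimmed amplicon inserts
are 306 bp (canonical), 398 bp (+cryptic exon) and 541 bp
(+cryptic +extension), matching the printed cluster lengths; with primers
included the products are 345/437/580 bp, the gel-band-scale sizes.
The insertion point falls at a codon boundary (177 ≡ 0 mod 3), so the
cryptic exon's first codon is its first three bases; the generator supports
any phase and rejects infeasible geometries (stop codon not fitting in the
exon, variant at or beyond the planted stop, in-frame insertion requested
with length ≢ 0 mod 3 — a planted internal stop makes downstream frame
irrelevant, which is why the default 92 bp exon is legal).

Two canonical haplotypes are planted for the amplicon fixture by eight
scattered exonic substitutions in exons 3–4 (>2% divergence over 306 bp, so
the haplotypes cannot merge at the 98% clustering threshold), mirroring the
two shared canonical clusters seen in the real data.

### Study conditions

The generators default to the study's stated sample sizes and rates:
WGS cohort 7 cases / 4 obligate carriers / 32 controls; RNA cohort
5 cases / 6 controls at 200 reads per sample; amplicon cohort 2 cases /
4 controls at 1,000 reads per sample with 1% i.i.d. substitution error
(substitution-only — no homopolymer indels, no quality-score realism, no
chimeras); genotyping panel n = 1,060 at q = 0.0118 with hom-alt redraw
(rare-disease ascertainment). The WGS cohort's background allele frequency
for the causal variant defaults to 0 among controls, matching the reported
control genotypes (all homozygous reference); the screening panel, not the
WGS controls, carries the population frequency. Amplicon mixtures are
0.5/0.5 canonical haplotypes in controls and 0.2/0.2/0.3/0.3
(A/B/cryptic/extended) in affected samples — three bands of comparable
intensity, as on the published gel. Parents can be modelled either as
`obligate_carrier` (enforced heterozygous; the default, the stricter
predicate) or `unknown` (excluded from the test, as the original
association run coded them).

What passing on this data shows — and does not show: the stages are exact
on substitution-dominated, boundary-clean evidence; they are not validated
against indel-rich nanopore error profiles, soft-clipped spliced
alignments, or multi-transcript loci.

## Segregation and association

The allelic Fisher test enumerates the hypergeometric distribution over the
table support directly and sums probabilities ≤ the observed table's with a
1e-12 relative tie tolerance; `scipy.stats.fisher_exact` serves as an
independent cross-check in the tests, never as the implementation. Missing
genotypes fail the segregation predicates by default (conservative); an
`allow_missing` flag relaxes this. Multiallelic sites are split per
alternate allele before filtering, genotypes recoded against the split
allele. The composed candidate chain runs segregation → association
threshold (p < 1e-11) → optional impact screen → cross-population
exclusion; the order is explicit configuration because the published
narrative interleaves these steps ambiguously, and the final candidate set
is dominated by MODIFIER-class variants, so the exclusion step operates on
all impact classes by default.

## Cryptic-exon calling

Evidence is consumed as BED12 block records rather than raw alignments,
keeping the stage testable without an aligner (a spliced-BAM adapter is an
extension point). Boundaries are merged-coverage bounds; junction support
(a read carrying both the intronic block and a flanking-exon block) is
reported but not required, since short-read data under-determines the
boundaries — exact boundaries belong to the amplicon stage. The thresholds
min_case_reads = 10 and max_control_fraction = 0.05 are package defaults
(no published values exist; identification was visual in the source study)
and are exposed in the configuration.

## Amplicon clustering, consensus and mapping

**Identity.** Global identity is defined as identical columns divided by
total columns of the optimal global alignment under match +1, mismatch −1,
gap −2 (gap columns count against identity). The published tool chain's
word-heuristic identity is not reproducible exactly; this DP definition is,
and it is oracle-testable. `global_identity` computes it with
`Bio.Align.PairwiseAligner`; the clustering loop accelerates it with (a)
the rigorous length-ratio upper bound identity ≤ min(L)/max(L), which
rejects cross-isoform comparisons outright, and (b) a vectorised Hamming
fast path for equal-length pairs, for which the gapless alignment is
score-optimal on substitution-dominated data. Equivalence of the fast path
with a pure-DP first-fit oracle is asserted on ≤50-read fixtures.

**Greedy clustering.** Reads sorted by length descending (ties by id
ascending) join the earliest-created cluster whose *founder read* (the
centroid) has identity ≥ 0.98, else found a new cluster. Cluster numbering
is therefore deterministic; the arbitrary cluster ids of the original
analysis (0/24/26/144) are not reproduced, only the multiset of
roles and lengths.

**Significance and classification.** A cluster is significant when it holds
strictly more than 10% of at least one sample's post-trim reads (the
published "total reads" is ambiguous between raw and trimmed; post-trim is
used because trimming rejections never reach the clustering). Significant
clusters are case-only if every control sample has <5 reads in them and
some case has ≥5; symmetric for control-only; else shared.

**Consensus.** 25 members are subsampled and laid out in a star multiple
alignment anchored on the centroid (each member pairwise-aligned to it) —
for same-length substitution-errored members this is column-identical to a
progressive MSA, and it is deterministic and cheap. Majority symbol per
column; ties break to the centroid's symbol (keeping the consensus in
A/C/G/T rather than IUPAC codes); majority-gap columns are deleted.

**Mapping.** Consensus sequences are decomposed into maximal near-exact
blocks against the gene span in coding orientation: 20-mer exact seeds,
bidirectional extension, at most 2 mismatches per block, and a mismatch is
bridged only when the following 10 bases (or all that remain before an
edge) match exactly — this tolerates the isolated planted G>C and haplotype
substitutions while keeping splice junctions boundary-exact. Because the
same bases can match on both sides of a junction, boundary placement is
disambiguated by splice-motif snapping: among sequence-consistent shifts of
the junction, the one placing GT after the donor and AG before the acceptor
wins (smallest shift on ties). Blocks inside annotated exons are canonical;
intronic blocks are novel; a canonical match running past an annotated exon
edge is reported as an extended boundary with its shift in bp.
`predict_amplicon_lengths` reports primer-excluded insert lengths by
default (the scale of trimmed-read cluster lengths); `include_primers=True`
gives product sizes.

**Quality.** Reads with mean quality < Q10 are dropped when quality is
present (upstream basecalling handles this in the real workflow); reads
without quality pass through.

### A note on cluster fragmentation

At 1% substitution error the expected Hamming distance between two reads of
the same 306 bp isoform is 2·306·0.01 ≈ 6.1, while 98% identity admits at
most ⌊0.02·306⌋ = 6 mismatches — the acceptance region boundary sits on the
distance distribution's mean. Founder-read centroids therefore fragment
each isoform group whenever the founder carries ≥4 errors, and a secondary
fragment of a 50%-abundance haplotype can cross the >10% significance rule.
The package measures this honestly: the exact (2 shared, 2 case-only)
inventory is recovered in roughly 30–50% of seeds, not near-always, and the
acceptance script reports the measured rate (`cluster_inventory_recovery_pct`).
The biologically meaningful calls are nonetheless stable: the case-only
isoforms and shared haplotypes are recovered with correct classes and exact
consensus sequences; what fluctuates is whether a haplotype's reads land in
one significant cluster or two. Centroid refinement (e.g. re-centering on
the consensus) would remove the fragmentation but would depart from the
single-pass founder-centroid algorithm this package reproduces.

## ORF analysis

Translation uses the standard genetic code only (no selenocysteine
recoding). `ptc_after_insertion` counts complete codons from the first
codon overlapping the first novel block up to, and excluding, the stop —
"a premature stop after 24 amino acids" on the default geometry. A
frameshift (insertion length ≢ 0 mod 3) is warned about only when
translation actually runs past the insertion; an internal stop keeps the
realised frame intact. The NMD flag uses the 55-nt last-junction heuristic
and is advisory, never a filter.

## Allele frequency

f̂ = (n_het + 2·n_homalt)/2n. The standard error is implemented with the
radical, SE = √(f̂(1−f̂)/2n): without the square root the quantity has the
units of a variance and cannot be a standard error; the estimate's metadata
records both readings. Calibration (bias < 3 SE of the mean, empirical SD
within 15% of the analytic SE over 500 simulated panels) is asserted in the
acceptance suite.

## Problem sizes

Defaults were chosen so the whole test suite runs in well under a minute of
CPU: 1,000 amplicon reads per sample (subsampling caps at 100,000, the
published depth), 200 spliced reads per sample, 60 decoy variants, 500
panel replicates, and 50–100 seeds for the cluster-inventory recovery
measurement. All are configuration, not constants.

## Known limitations

- Single-transcript gene models; no genome-wide scans.
- Substitution-only error model; no indels, chimeras or quality realism.
- The exclusion flow and clustering identity definitions are reconstructions
  of under-specified published procedures (documented choices above).
- HGVS naming covers intronic positions within the coding region of the
  transcript; exonic and UTR-anchored names are out of scope.
- No quantitative differential expression (the decreased-expression result
  in the source study is acknowledged, not re-fit) and no structural-variant
  detection.
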