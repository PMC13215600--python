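# crypticex

Deep-intronic variants can create cryptic (pseudo-)exons: intronic segments
spliced into the mRNA only on the variant haplotype, often introducing a
premature termination codon (PTC) and triggering nonsense-mediated decay.
`crypticex` is a tested, reusable implementation of the inference chain used
to identify such a variant in an autosomal recessive disease — written for
the veterinary/comparative-genomics setting of Equine Juvenile Spinocerebellar
Ataxia (EJSCA) in Quarter Horses, where an FDXR intronic G>C substitution
(`FDXR-203` c.177+1778G>C) activates a cryptic exon in intron 2 — but the
machinery is generic over any single-transcript locus.

The pipeline covers five stages, each usable as a library module or CLI
subcommand:

1. **Segregation and association** (`crypticex.segregation`) — recessive
   predicates over a multi-sample VCF (cases homozygous-alternate, obligate
   carriers heterozygous, no hom-alt control), a two-sided allelic Fisher
   exact test on the 2×2 case/control allele-count table
   (p = Σ P(k) over all tables with fixed margins whose probability ≤ the
   observed table's), SnpEff impact screening, cross-population exclusion,
   candidate-region definition, and HGVS intronic naming (c.X+Y / c.X−Y by
   the nearest-exon rule).
2. **Cryptic-exon calling** (`crypticex.cryptic`) — merged intronic coverage
   from spliced-read block records (BED12), called when case support ≥ 10
   reads and control leakage ≤ 5% of case support.
3. **Amplicon isoform analysis** (`crypticex.amplicon`) — per-sample
   subsampling, exact primer trimming, greedy centroid clustering at 98%
   global identity (match +1 / mismatch −1 / gap −2; identical columns over
   all alignment columns), the ">10% of at least one sample" significance
   rule, 25-member majority consensus, case/control cluster classification,
   and consensus-to-genome block decomposition with splice-motif-aware
   junction snapping.
4. **ORF analysis** (`crypticex.orf`) — transcript assembly from exon
   structures, standard-code translation, PTC counting after an insertion,
   and an advisory 55-nt NMD flag.
5. **Population genetics** (`crypticex.popgen`) — the allele-counting
   estimator f̂ = (n_het + 2·n_homalt)/2n with binomial SE
   √(f̂(1−f̂)/2n), and the 2^−ΔΔCt qPCR fold change.

A first-class synthetic-data module (`crypticex.synthetic`) builds a toy
five-exon locus whose planted truth mirrors the study geometry — a 92 bp
cryptic exon (amplicon inserts 306/398/541 bp), the causal G>C at the exon's
eighth base, 1778 bp downstream of the exon ending at c.177, and a TGA
exactly 24 codons after the cryptic exon's first codon — so every stage is
testable end to end without external data.

## Worked example

```sh
crypticex run-all --outdir demo --seed 2
```

prints (abridged):

```
candidate variants after filtering: 1
candidate region: chrT:3505-3505 (span 0 bp)
causal variant HGVS: c.177+1778G>C
cryptic-exon calls: 1
variant offset inside cryptic exon: 8
amplicon clusters: 852 total, 4 significant (2 shared, 2 case-only)
translation: stop TGA after 24 aa (PTC=True, NMD candidate=True)
allele frequency: 0.0127 (SE 0.0024)
```

Reading the report: of the simulated cohort VCF (planted causal variant plus
60 decoys over 7 cases, 4 obligate carriers, 32 controls) exactly one
variant survives the segregation + association chain; its HGVS name matches
the planted truth. The spliced-read evidence yields one cryptic-exon call
whose boundaries contain the variant at its eighth base. The long-read
amplicon chain finds two significant clusters shared by all samples (the two
306 bp canonical haplotypes) and two present only in affected samples (the
398 bp cryptic and 541 bp cryptic+extended-acceptor isoforms). Translating
the cryptic isoform shows an in-frame TGA 24 amino acids after the cryptic
exon's first codon, upstream of the last exon junction by more than 55 nt
(an NMD candidate). The simulated 1,060-animal genotyping panel at carrier
frequency q = 0.0118 gives f̂ = 0.0127 with binomial SE 0.0024.

Every subcommand is also available standalone (`crypticex segregate`,
`cryptic`, `amplicon`, `allelefreq`, `ddct`); see `crypticex --help`.

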