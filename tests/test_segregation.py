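import math
import random
from fractions import Fraction

import pytest
from scipy.stats import fisher_exact

from crypticex import datasets, study
from crypticex import segregation as seg
from crypticex import synthetic as syn
from crypticex.segregation import (
    CohortDesign,
    VariantRecord,
    allelic_fisher,
    cross_population_exclude,
    define_candidate_region,
    hgvs_intronic_name,
    impact_filter,
    parse_ann,
    parse_vcf,
    recessive_segregation_filter,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=ANN,Number=.,Type=String,Description="x">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


class TestParseVcf:
    def test_basic_genotype_words(self):
        text = VCF_HEADER + "11\t6963986\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\n"
        (rec,) = parse_vcf(text)
        assert (rec.chrom, rec.pos, rec.ref, rec.alt) == ("11", 6963986, "C", "T")
        assert rec.genotypes == {"s1": "homalt", "s2": "het", "s3": "homref"}

    def test_missing_genotype_preserved(self):
        text = VCF_HEADER + "11\t10\t.\tA\tG\t.\t.\t.\tGT\t./.\t0/1\t1|1\n"
        (rec,) = parse_vcf(text)
        assert rec.genotypes["s1"] == "missing"
        assert rec.genotypes["s3"] == "homalt"  # phased separator accepted

    def test_multiallelic_split(self):
        text = VCF_HEADER + "11\t10\t.\tA\tT,G\t.\t.\t.\tGT\t1/2\t0/2\t0/0\n"
        recs = parse_vcf(text)
        assert [(r.pos, r.alt) for r in recs] == [(10, "T"), (10, "G")]
        r_t, r_g = recs
        assert r_t.genotypes["s1"] == "het" and r_g.genotypes["s1"] == "het"
        assert r_t.genotypes["s2"] == "homref" and r_g.genotypes["s2"] == "het"

    def test_malformed_row_names_line(self):
        text = VCF_HEADER + "11\t10\t.\tA\tG\t.\t.\t.\tGT\t0/0\n"
        with pytest.raises(seg.VcfParseError, match="line 5"):
            parse_vcf(text)

    def test_agrees_with_pysam_on_cohort_vcf(self, tmp_path, wgs_design, plus_locus):
        pysam = pytest.importorskip("pysam")
        import crypticex.io as cio

        _, gene, truth = plus_locus
        variants = study.cohort_variants(truth, gene, n_decoys=20, seed=3)
        gts = syn.simulate_cohort_genotypes(wgs_design, variants, 0.1, seed=4)
        path = tmp_path / "c.vcf"
        cio.write_cohort_vcf(path, "chrT", 8000, variants, gts, list(wgs_design.roles))
        ours = parse_vcf(path)
        theirs = list(pysam.VariantFile(str(path)).fetch())
        assert len(ours) == len(theirs)
        word = {(0, 0): "homref", (0, 1): "het", (1, 1): "homalt"}
        for a, b in zip(ours, theirs):
            assert (a.chrom, a.pos, a.ref, a.alt) == (
                b.chrom, b.pos, b.ref, b.alts[0])
            for s in wgs_design.roles:
                assert a.genotypes[s] == word[tuple(sorted(b.samples[s]["GT"]))]


class TestParseAnn:
    @pytest.mark.parametrize(
        "text,gene,impact",
        [
            ("T|intron_variant|MODIFIER|FDXR", "FDXR", "MODIFIER"),
            ("T|synonymous_variant|LOW|FADS6", "FADS6", "LOW"),
        ],
    )
    def test_single_entry(self, text, gene, impact):
        (a,) = parse_ann(text)
        assert (a.gene, a.impact) == (gene, impact)

    def test_empty_is_empty_list(self):
        assert parse_ann("") == []

    def test_multiple_entries_and_unknown_impact(self):
        assert len(parse_ann("T|a|HIGH|g1,G|b|LOW|g2")) == 2
        with pytest.raises(ValueError):
            parse_ann("T|a|SEVERE|g")


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exact-rational enumeration of all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(k):
        return (
            Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = table_prob(a)
    return float(sum(table_prob(k) for k in range(lo, hi + 1) if table_prob(k) <= p_obs))


class TestAllelicFisher:
    def test_worked_examples(self):
        assert allelic_fisher(2, 0, 0, 2) == pytest.approx(1 / 3)
        assert allelic_fisher(5, 5, 5, 5) == pytest.approx(1.0)
        assert allelic_fisher(14, 0, 0, 64) == pytest.approx(1 / math.comb(78, 14), rel=1e-9)

    def test_all_zero_table_is_one(self):
        assert allelic_fisher(0, 0, 0, 0) == 1.0

    def test_matches_exact_enumeration_for_small_margins(self):
        rng = random.Random(0)
        for _ in range(200):
            a, b, c, d = (rng.randrange(0, 16) for _ in range(4))
            if a + b + c + d == 0:
                continue
            assert allelic_fisher(a, b, c, d) == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), rel=1e-9, abs=1e-300
            )

    def test_cross_checked_against_scipy(self):
        rng = random.Random(1)
        for _ in range(100):
            a, b, c, d = (rng.randrange(0, 30) for _ in range(4))
            if a + b == 0 or c + d == 0:
                continue
            ours = allelic_fisher(a, b, c, d)
            theirs = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)


def _mk(pos, gts, impact="MODIFIER", gene="FDXR", alt="C", ref="G", chrom="11"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=dict(gts),
        annotations=[seg.VariantAnnotation(gene, "intron_variant", impact, alt)],
    )


class TestSegregationFilter:
    def setup_method(self):
        self.design = CohortDesign(
            {"a1": "case", "a2": "case", "p1": "obligate_carrier", "c1": "control"}
        )

    def test_perfect_segregation_kept(self):
        v = _mk(10, {"a1": "homalt", "a2": "homalt", "p1": "het", "c1": "homref"})
        assert recessive_segregation_filter([v], self.design) == [v]

    @pytest.mark.parametrize(
        "bad", [{"a1": "het"}, {"p1": "homalt"}, {"c1": "homalt"}, {"a1": "missing"}]
    )
    def test_violations_dropped(self, bad):
        gts = {"a1": "homalt", "a2": "homalt", "p1": "het", "c1": "homref"} | bad
        assert recessive_segregation_filter([_mk(10, gts)], self.design) == []

    def test_allow_missing_relaxes(self):
        gts = {"a1": "homalt", "a2": "missing", "p1": "het", "c1": "missing"}
        v = _mk(10, gts)
        assert recessive_segregation_filter([v], self.design) == []
        assert recessive_segregation_filter([v], self.design, allow_missing=True) == [v]

    def test_unknown_role_ignored(self):
        design = CohortDesign({"a1": "case", "u1": "unknown"})
        v = _mk(10, {"a1": "homalt", "u1": "homref"})
        assert recessive_segregation_filter([v], design) == [v]

    def test_agrees_with_bruteforce_on_random_cohorts(self):
        rng = random.Random(7)
        roles = {f"s{i}": rng.choice(["case", "obligate_carrier", "control", "unknown"])
                 for i in range(12)}
        roles["s0"] = "case"
        design = CohortDesign(roles)
        words = ["homref", "het", "homalt", "missing"]
        variants = [
            _mk(i + 1, {s: rng.choice(words) for s in roles}) for i in range(1000)
        ]

        def brute(v):
            for s, r in roles.items():
                g = v.genotypes[s]
                if r == "case" and g != "homalt":
                    return False
                if r == "obligate_carrier" and g != "het":
                    return False
                if r == "control" and g in ("homalt", "missing"):
                    return False
            return True

        expected = [v for v in variants if brute(v)]
        assert recessive_segregation_filter(variants, design) == expected


class TestImpactAndExclusion:
    def test_impact_filter_basics(self):
        v_mod = _mk(1, {}, impact="MODIFIER")
        v_high = _mk(2, {}, impact="HIGH")
        assert impact_filter([v_mod, v_high], {"HIGH", "MODERATE"}) == [v_high]
        both = [v_mod, v_high]
        assert impact_filter(both, seg.IMPACTS) == both  # identity case

    def test_filters_idempotent_and_order_preserving(self):
        rng = random.Random(3)
        variants = [
            _mk(i, {}, impact=rng.choice(list(seg.IMPACTS))) for i in range(1, 50)
        ]
        obs = {v.key: {"Arabian"} for v in variants if rng.random() < 0.5}
        once = impact_filter(variants, {"MODIFIER", "LOW"})
        assert impact_filter(once, {"MODIFIER", "LOW"}) == once
        kept = cross_population_exclude(variants, obs, "Quarter Horse")
        assert cross_population_exclude(kept, obs, "Quarter Horse") == kept
        assert kept == [v for v in variants if v in kept]  # original order

    def test_exclusion_rules(self):
        v = _mk(5, {})
        assert cross_population_exclude([v], {v.key: {"Arabian"}}, "QH") == []
        assert cross_population_exclude([v], {}, "QH") == [v]
        assert cross_population_exclude([v], {v.key: {"QH"}}, "QH") == [v]

    def test_synthetic_association_table_leaves_nine(self):
        variants, obs = datasets.synthetic_association_table(seed=0)
        assert len(variants) == 77
        kept = cross_population_exclude(variants, obs, datasets.HOME_BREED)
        assert len(kept) == 9
        assert {v.pos for v in kept} == {
            p for _, p, *_ in datasets.EJSCA_CANDIDATE_VARIANTS
        }


class TestCandidateRegion:
    def test_published_candidates_span(self):
        region = define_candidate_region(datasets.candidate_variant_records())
        assert (region.chrom, region.start, region.end) == ("11", 6963986, 7045999)
        assert region.span == 82013
        assert region.n_variants == 9

    def test_degenerate_regions(self):
        assert define_candidate_region([_mk(5, {})]).span == 0
        vs = [_mk(5, {}), _mk(6, {})]
        assert define_candidate_region(vs).span == 1

    def test_multiple_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            define_candidate_region([_mk(5, {}), _mk(6, {}, chrom="12")])


class TestHgvs:
    def test_planted_variant_name(self, plus_locus):
        _, gene, truth = plus_locus
        v = _mk(truth.variant_position, {}, alt="C", ref="G", chrom="chrT")
        name = hgvs_intronic_name(v, gene)
        assert name.rendered == "c.177+1778G>C" == truth.expected_hgvs
        assert name.anchor_cdna_pos == 177 and name.offset == 1778

    def test_minus_strand_name_uses_coding_alleles(self, minus_locus):
        _, gene, truth = minus_locus
        v = _mk(truth.variant_position, {}, alt=truth.variant_alt,
                ref=truth.variant_ref, chrom="chrT")
        assert hgvs_intronic_name(v, gene).rendered == "c.177+1778G>C"

    def test_first_base_after_exon(self, plus_locus):
        _, gene, truth = plus_locus
        pos = gene.exons[1][1] + 1  # 1-based: first intronic base
        name = hgvs_intronic_name(_mk(pos, {}, chrom="chrT"), gene)
        assert name.rendered == "c.177+1G>C"

    def test_near_downstream_exon_uses_minus_form(self, plus_locus):
        _, gene, truth = plus_locus
        pos = gene.exons[2][0] - 5 + 1  # 5 bp before exon 3 (1-based)
        name = hgvs_intronic_name(_mk(pos, {}, chrom="chrT"), gene)
        # exon 3 starts at cDNA coding position 178
        assert name.rendered == "c.178-5G>C"

    def test_exonic_position_rejected(self, plus_locus):
        _, gene, _ = plus_locus
        with pytest.raises(ValueError, match="exonic"):
            hgvs_intronic_name(_mk(gene.exons[1][0] + 1, {}, chrom="chrT"), gene)


class TestComposedChain:
    def test_planted_variant_always_survives(self, wgs_design, plus_locus):
        _, gene, truth = plus_locus
        for seed in range(10):
            variants = study.cohort_variants(truth, gene, n_decoys=40, seed=seed)
            gts = syn.simulate_cohort_genotypes(wgs_design, variants, 0.0, seed=seed)
            records = [
                _mk(v.pos, g, impact=v.impact, gene=v.gene, alt=v.alt, ref=v.ref,
                    chrom="chrT")
                for v, g in zip(variants, gts)
            ]
            kept, assoc = seg.candidate_filter_chain(records, wgs_design)
            assert truth.variant_position in {v.pos for v in kept}
            p = assoc[("chrT", truth.variant_position, "C")].p_allelic
            assert p == pytest.approx(1 / math.comb(78, 14), rel=1e-9)

    def test_decoy_survival_is_rare(self, wgs_design, plus_locus):
        # a decoy at frequency q >= 0.05 segregates perfectly with probability
        # (q^2)^7 (2q(1-q))^4 (1-q^2)^32 < 4e-16, so across 200 replicates of
        # 40 decoys the expected survivor count is far below one
        _, gene, truth = plus_locus
        survivors = 0
        for seed in range(200):
            variants = study.cohort_variants(truth, gene, n_decoys=40, seed=seed)
            gts = syn.simulate_cohort_genotypes(wgs_design, variants, 0.0, seed=seed)
            records = [
                _mk(v.pos, g, alt=v.alt, ref=v.ref, chrom="chrT")
                for v, g in zip(variants, gts)
            ]
            kept, _ = seg.candidate_filter_chain(records, wgs_design)
            survivors += sum(1 for v in kept if v.pos != truth.variant_position)
        assert survivors == 0
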