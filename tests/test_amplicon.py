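import random

import numpy as np
import pytest

from crypticex import study
from crypticex import synthetic as syn
from crypticex.amplicon import (
    AmpliconRead,
    PrimerPair,
    classify_clusters,
    consensus,
    global_identity,
    greedy_cluster,
    map_consensus,
    predict_amplicon_lengths,
    primer_footprints,
    quality_filter,
    significant_clusters,
    subsample_reads,
    trim_all,
    trim_primers,
)
from crypticex.genemodel import revcomp


def _read(i, seq, sample="s1", q=30.0):
    return AmpliconRead(id=f"{sample}:{i:04d}", sample=sample, sequence=seq, mean_quality=q)


PRIMERS = PrimerPair("CTTCTACACGGCCCAACACC", "GAGCCCATTGTACCAGCCC")


class TestTrim:
    def test_forward_orientation(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"
        read = _read(0, PRIMERS.forward + insert + revcomp(PRIMERS.reverse))
        assert trim_primers(read, PRIMERS) == (insert, None)

    def test_reverse_orientation(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"
        read = _read(0, revcomp(PRIMERS.forward + insert + revcomp(PRIMERS.reverse)))
        assert trim_primers(read, PRIMERS) == (insert, None)

    def test_single_mismatch_rejected(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"
        bad_f = "A" + PRIMERS.forward[1:]
        read = _read(0, bad_f + insert + revcomp(PRIMERS.reverse))
        seq, reason = trim_primers(read, PRIMERS)
        assert seq is None and reason is not None
        good = PRIMERS.forward + insert + "A" + revcomp(PRIMERS.reverse)[1:]
        assert trim_primers(_read(1, good), PRIMERS)[0] is None

    def test_trim_tallies_rejections_per_sample(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"
        ok = _read(0, PRIMERS.forward + insert + revcomp(PRIMERS.reverse), sample="a")
        bad = _read(1, "T" * 60, sample="b")
        trimmed, rejected = trim_all([ok, bad], PRIMERS)
        assert [r.sequence for r in trimmed] == [insert]
        assert list(rejected) == ["b"]

    def test_quality_filter(self):
        reads = [_read(0, "ACGT", q=9.0), _read(1, "ACGT", q=30.0), _read(2, "ACGT", q=None)]
        assert [r.id for r in quality_filter(reads)] == ["s1:0001", "s1:0002"]


class TestSubsample:
    def test_all_reads_kept_in_order_when_n_large(self):
        reads = [_read(i, "ACGT") for i in range(10)]
        assert subsample_reads(reads, 100, seed=0) == reads

    def test_deterministic_and_per_sample(self):
        reads = [_read(i, "ACGT", sample=f"s{i % 2}") for i in range(1000)]
        a = subsample_reads(reads, 10, seed=5)
        b = subsample_reads(reads, 10, seed=5)
        assert a == b
        assert sum(1 for r in a if r.sample == "s0") == 10
        assert sum(1 for r in a if r.sample == "s1") == 10

    def test_selection_is_uniform(self):
        reads = [_read(i, "ACGT") for i in range(100)]
        hits = np.zeros(100)
        for rep in range(200):
            for r in subsample_reads(reads, 50, seed=rep):
                hits[int(r.id.split(":")[1])] += 1
        se = (200 * 0.5 * 0.5) ** 0.5
        assert (np.abs(hits - 100) < 4 * se).all()


class TestGlobalIdentity:
    def test_worked_examples(self):
        assert global_identity("ACGTACGT", "ACGTACGT") == 1.0
        assert global_identity("ACGT", "ACGA") == 0.75
        assert global_identity("ACGT", "ACG") == 0.75  # one gap column of four

    def test_symmetric(self):
        rng = random.Random(0)
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randrange(5, 40)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randrange(5, 40)))
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")


def oracle_cluster(reads, threshold):
    """Independent first-fit clustering over pure-DP identity."""
    order = sorted(reads, key=lambda r: (-len(r.sequence), r.id))
    clusters = []  # (centroid_seq, [ids])
    for r in order:
        for cs, ids in clusters:
            if global_identity(r.sequence, cs) >= threshold:
                ids.append(r.id)
                break
        else:
            clusters.append((r.sequence, [r.id]))
    return [tuple(ids) for _, ids in clusters]


class TestGreedyCluster:
    def test_identical_reads_form_one_cluster(self):
        reads = [_read(i, "ACGT" * 30) for i in range(10)]
        (c,) = greedy_cluster(reads)
        assert c.size == 10 and c.centroid_read == "s1:0000"
        assert c.mean_length == 120

    def test_distinct_groups_form_two_clusters(self):
        rng = random.Random(2)
        base = "".join(rng.choice("ACGT") for _ in range(200))
        other = list(base)
        for p in range(0, 200, 10):  # 90% identity
            other[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[p]]
        reads = [_read(i, base) for i in range(5)]
        reads += [_read(i + 5, "".join(other)) for i in range(5)]
        clusters = greedy_cluster(reads, threshold=0.98)
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [5, 5]

    def test_matches_bruteforce_oracle_on_noisy_reads(self, plus_locus):
        contig, gene, truth = plus_locus
        primers = study.default_primers()
        inserts = syn.amplicon_inserts(contig, gene, truth, primers)
        reads = syn.simulate_amplicon_reads(
            inserts,
            {"s1": {"canonical_A": 0.4, "canonical_B": 0.3, "cryptic": 0.3}},
            primers, error_rate=0.01, n_reads=50, seed=8)
        trimmed, _ = trim_all(reads, primers)
        got = [tuple(c.member_ids) for c in greedy_cluster(trimmed, 0.98)]
        assert got == oracle_cluster(trimmed, 0.98)

    def test_partition_and_centroid_identity_invariants(self, plus_locus):
        contig, gene, truth = plus_locus
        primers = study.default_primers()
        inserts = syn.amplicon_inserts(contig, gene, truth, primers)
        reads = syn.simulate_amplicon_reads(
            inserts, {"s1": {"canonical_A": 0.5, "cryptic_extended": 0.5}},
            primers, error_rate=0.005, n_reads=120, seed=9)
        trimmed, _ = trim_all(reads, primers)
        by_id = {r.id: r for r in trimmed}
        clusters = greedy_cluster(trimmed, 0.98)
        seen = []
        for c in clusters:
            centroid = by_id[c.centroid_read].sequence
            for mid in c.member_ids:
                assert global_identity(by_id[mid].sequence, centroid) >= 0.98
            seen.extend(c.member_ids)
        assert sorted(seen) == sorted(by_id)  # disjoint and exhaustive


class TestSignificance:
    def _cluster(self, counts, cid=0):
        from crypticex.amplicon import Cluster

        return Cluster(id=cid, centroid_read="x", member_ids=["x"],
                       per_sample_counts=counts)

    def test_eleven_percent_kept(self):
        c = self._cluster({"a": 11})
        assert significant_clusters([c], {"a": 100, "b": 100}) == [c]

    def test_exactly_ten_percent_dropped(self):
        c = self._cluster({"a": 10, "b": 10})
        assert significant_clusters([c], {"a": 100, "b": 100}) == []

    def test_zero_total_sample_excluded(self):
        c = self._cluster({"a": 3})
        assert significant_clusters([c], {"a": 0}) == []

    def test_singleton_noise_dropped(self):
        cs = [self._cluster({"a": 1}, cid=i) for i in range(50)]
        assert significant_clusters(cs, {"a": 1000}) == []


class TestConsensus:
    def test_error_free_cluster_reproduces_insert(self, plus_locus):
        contig, gene, truth = plus_locus
        primers = study.default_primers()
        inserts = syn.amplicon_inserts(contig, gene, truth, primers)
        reads = syn.simulate_amplicon_reads(
            inserts, {"s1": {"cryptic": 1.0}}, primers, error_rate=0.0,
            n_reads=30, seed=3)
        trimmed, _ = trim_all(reads, primers)
        (c,) = greedy_cluster(trimmed)
        cons = consensus(c, {r.id: r for r in trimmed}, k=25, seed=0)
        assert cons.sequence == inserts["cryptic"]
        assert all(s == 1.0 for s in cons.support_per_column)

    @pytest.mark.parametrize("seed", range(5))
    def test_one_percent_errors_corrected_by_majority(self, seed, plus_locus):
        contig, gene, truth = plus_locus
        primers = study.default_primers()
        inserts = syn.amplicon_inserts(contig, gene, truth, primers)
        reads = syn.simulate_amplicon_reads(
            inserts, {"s1": {"canonical_A": 1.0}}, primers, error_rate=0.01,
            n_reads=120, seed=seed)
        trimmed, _ = trim_all(reads, primers)
        clusters = greedy_cluster(trimmed)
        big = max(clusters, key=lambda c: c.size)
        cons = consensus(big, {r.id: r for r in trimmed}, k=25, seed=seed)
        assert cons.sequence == inserts["canonical_A"]

    def test_singleton_cluster_is_its_member(self):
        r = _read(0, "ACGT" * 20)
        (c,) = greedy_cluster([r])
        cons = consensus(c, {r.id: r}, k=25, seed=0)
        assert cons.sequence == r.sequence


class TestClassify:
    def test_planted_classes(self, amp_design):
        from crypticex.amplicon import Cluster

        shared = Cluster(0, "x", ["x"], {"case01": 50, "control01": 50, "control02": 40})
        case_only = Cluster(1, "y", ["y"], {"case01": 80, "case02": 60, "control01": 2})
        ctrl_only = Cluster(2, "z", ["z"], {"control01": 80, "control02": 60})
        classes = classify_clusters([shared, case_only, ctrl_only], amp_design)
        assert classes == {0: "shared", 1: "case_only", 2: "control_only"}

    def test_empty_control_arm_warns(self):
        from crypticex.amplicon import Cluster
        from crypticex.segregation import CohortDesign

        design = CohortDesign({"a": "case"})
        c = Cluster(0, "x", ["x"], {"a": 10})
        with pytest.warns(UserWarning):
            classes = classify_clusters([c], design)
        assert classes[0] == "case_only"


class TestMapConsensus:
    @pytest.fixture(params=["+", "-"])
    def locus(self, request, plus_locus, minus_locus):
        return plus_locus if request.param == "+" else minus_locus

    def _insert(self, locus, name):
        contig, gene, truth = locus
        return syn.amplicon_inserts(contig, gene, truth, study.default_primers())[name]

    def test_canonical_maps_to_exons_only(self, locus):
        contig, gene, truth = locus
        s = map_consensus(self._insert(locus, "canonical_A"), contig, gene)
        assert s.novel_blocks == [] and s.extended_boundaries == []
        for b in s.exon_intervals:
            assert any(es <= b[0] and b[1] <= ee for es, ee in gene.exons)
        assert sum(e - s0 for s0, e in s.exon_intervals) == 306

    def test_cryptic_maps_novel_block_boundary_exact(self, locus):
        contig, gene, truth = locus
        s = map_consensus(self._insert(locus, "cryptic"), contig, gene)
        assert s.novel_blocks == [truth.cryptic_exon_interval]
        assert s.extended_boundaries == []

    def test_extended_acceptor_reported(self, locus):
        contig, gene, truth = locus
        s = map_consensus(self._insert(locus, "cryptic_extended"), contig, gene)
        assert s.novel_blocks == [truth.cryptic_exon_interval]
        assert s.extended_boundaries == [(3, 143)]

    def test_haplotype_b_mismatches_are_bridged(self, plus_locus):
        contig, gene, truth = plus_locus
        s = map_consensus(self._insert(plus_locus, "canonical_B"), contig, gene)
        assert s.novel_blocks == []
        placed = sum(e - s0 for s0, e in s.exon_intervals)
        assert placed >= 0.9 * 306

    def test_unmappable_consensus_rejected(self, plus_locus):
        contig, gene, _ = plus_locus
        rng = random.Random(0)
        junk = "".join(rng.choice("ACGT") for _ in range(200))
        with pytest.raises(ValueError, match="unmappable"):
            map_consensus(junk, contig, gene)


class TestPredictLengths:
    def test_fixture_lengths(self, plus_locus):
        contig, gene, truth = plus_locus
        primers = study.default_primers()
        fp = primer_footprints(contig, gene, primers)
        inserts = syn.amplicon_inserts(contig, gene, truth, primers)
        structures = [
            map_consensus(inserts[n], contig, gene)
            for n in ("canonical_A", "cryptic", "cryptic_extended")
        ]
        assert predict_amplicon_lengths(structures, fp) == [306, 398, 541]
        # gel-band-scale sizes from the full planted structures
        full = [truth.isoform_structures[n]
                for n in ("canonical", "cryptic", "cryptic_extended")]
        with_primers = predict_amplicon_lengths(full, fp, include_primers=True)
        assert with_primers == [345, 437, 580]

    def test_empty_isoform_list(self, plus_locus):
        contig, gene, _ = plus_locus
        fp = primer_footprints(contig, gene, study.default_primers())
        assert predict_amplicon_lengths([], fp) == []

    def test_isoform_missing_primer_exon_skipped(self, plus_locus):
        from crypticex.amplicon import IsoformStructure

        contig, gene, _ = plus_locus
        fp = primer_footprints(contig, gene, study.default_primers())
        partial = IsoformStructure(exon_intervals=[gene.exons[2]])
        with pytest.warns(UserWarning):
            assert predict_amplicon_lengths([partial], fp) == []
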