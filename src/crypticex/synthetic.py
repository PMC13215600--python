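"""Synthetic locus, cohort, read and panel generators with a recorded truth.

The generator plants the geometry of a recessive splicing disease: a gene of
five or more exons, a deep-intronic G>C variant sitting at a known offset
inside a cryptic exon that is spliced in only on the variant haplotype, an
optional extended acceptor on the exon downstream of the cryptic exon, and a
premature TGA a fixed number of codons after the cryptic exon's first codon.
Every derived quantity a downstream stage should recover (variant position,
cryptic-exon interval, HGVS name, PTC codon count, per-genotype isoform
sets) is recorded in a :class:`PlantedTruth` serialized next to the outputs.

All generators take one integer seed and are bitwise deterministic; no
global RNG state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .genemodel import GeneModel, Interval, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOPS = {"TAA", "TAG", "TGA"}

# Published RT-PCR primer pair used for the amplicon fixtures (forward primer
# anneals in exon 2, reverse primer in exon 5 of the modelled transcript).
DEFAULT_FORWARD_PRIMER = "CTTCTACACGGCCCAACACC"
DEFAULT_REVERSE_PRIMER = "GAGCCCATTGTACCAGCCC"


@dataclass
class CrypticExonSpec:
    """Geometry of the planted cryptic exon.

    ``intron_index`` is 1-based in transcription order; ``offset_into_intron``
    is the 0-based distance from the intron's first base to the exon's first
    base; ``variant_offset_in_exon`` is 1-based; ``stop_after_aa`` plants an
    in-frame TGA exactly that many codons after the exon's first codon.
    """

    intron_index: int = 2
    offset_into_intron: int = 1770
    length: int = 92
    variant_offset_in_exon: int = 8
    stop_after_aa: int | None = 24


@dataclass
class LocusSpec:
    """Blueprint for the toy locus.

    Defaults mirror the study geometry: the canonical amplicon insert between
    the exon-2 and exon-5 primers is 306 bp, the cryptic exon adds 92 bp
    (398 bp insert) and the extended exon-3 acceptor a further 143 bp
    (541 bp insert); the variant is the eighth base of the cryptic exon,
    1778 bp downstream of the exon ending at c.177.
    """

    contig_name: str = "chrT"
    contig_length: int = 8000
    exon_lengths: list[int] = field(default_factory=lambda: [100, 127, 120, 100, 150])
    intron_lengths: list[int] = field(default_factory=lambda: [500, 4000, 300, 300])
    strand: str = "+"
    cds_start_exon_offset: int = 50
    cds_end_exon_offset: int = 101  # offset past the last exon's start
    cryptic_exon: CrypticExonSpec | None = field(default_factory=CrypticExonSpec)
    extended_acceptor_shift: int = 143
    gene_offset: int = 1000
    gene_name: str = "FDXR"
    transcript_label: str = "FDXR-203"
    forward_primer_exon_offset: int = 77  # F primer start within exon 2
    reverse_primer_exon_offset: int = 56  # rc(R) start within the last exon
    seed: int = 0

    @property
    def exon_count(self) -> int:
        return len(self.exon_lengths)

    def validate(self) -> None:
        if self.exon_count < 2 or len(self.intron_lengths) != self.exon_count - 1:
            raise ValueError("need >=2 exons and exon_count-1 introns")
        if any(x < 1 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError("exon/intron lengths must be >= 1")
        span = sum(self.exon_lengths) + sum(self.intron_lengths)
        if self.gene_offset + span > self.contig_length:
            raise ValueError("gene does not fit on the contig")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ce = self.cryptic_exon
        if ce is not None and ce.length > 0:
            if not 1 <= ce.intron_index <= len(self.intron_lengths):
                raise ValueError("cryptic exon intron_index out of range")
            ilen = self.intron_lengths[ce.intron_index - 1]
            if ce.offset_into_intron < 4 or ce.offset_into_intron + ce.length > ilen - 4:
                raise ValueError("cryptic exon must leave >=4 bp intronic margin on each side")
            if not 1 <= ce.variant_offset_in_exon <= ce.length:
                raise ValueError("variant_offset_in_exon outside the cryptic exon")
            if ce.stop_after_aa is None and ce.length % 3 != 0:
                raise ValueError("in-frame insertion requested but exon length % 3 != 0")
            if self.extended_acceptor_shift:
                if ce.intron_index >= self.exon_count:
                    raise ValueError("no downstream exon to extend")
                gap = ilen - (ce.offset_into_intron + ce.length)
                if self.extended_acceptor_shift + 4 > gap - 2:
                    raise ValueError("extended acceptor overlaps the cryptic exon")


@dataclass
class PlantedTruth:
    """Ground truth recorded by :func:`build_toy_locus` (plus-strand coords)."""

    contig_name: str
    variant_position: int  # 1-based
    variant_ref: str
    variant_alt: str
    cryptic_exon_interval: Interval | None
    expected_hgvs: str | None
    expected_ptc_aa: int | None
    isoform_set_per_genotype: dict[str, list[str]]
    isoform_structures: dict[str, list[Interval]]
    canonical_mrna: str
    cryptic_mrna: str | None
    haplotype_b_positions: list[int]  # 0-based genomic substitution sites
    panel_counts: tuple[int, int, int] | None = None

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["cryptic_exon_interval"] = (
            list(self.cryptic_exon_interval) if self.cryptic_exon_interval else None
        )
        d["isoform_structures"] = {
            k: [list(iv) for iv in v] for k, v in self.isoform_structures.items()
        }
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "PlantedTruth":
        d = dict(d)
        if d.get("cryptic_exon_interval"):
            d["cryptic_exon_interval"] = tuple(d["cryptic_exon_interval"])
        d["isoform_structures"] = {
            k: [tuple(iv) for iv in v] for k, v in d["isoform_structures"].items()
        }
        if d.get("panel_counts"):
            d["panel_counts"] = tuple(d["panel_counts"])
        return cls(**d)


# ---------------------------------------------------------------------------
# locus construction


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _scrub_stops(seq: np.ndarray, coding_pos: np.ndarray, protected: set[int]) -> None:
    """Remove in-frame stops from the CDS, editing only unprotected bases.

    ``coding_pos`` lists genomic (array) indices of coding bases in frame
    order; the final codon (the genuine stop) is left alone.
    """
    n_codons = len(coding_pos) // 3
    for j in range(n_codons - 1):
        idx = coding_pos[3 * j : 3 * j + 3]
        codon = seq[idx].tobytes().decode()
        if codon in STOPS:
            free = [i for i in idx[::-1] if int(i) not in protected]
            if not free:
                raise ValueError("stop codon falls entirely inside a protected primer footprint")
            seq[free[0]] = ord("C")  # no stop codon contains C


def build_toy_locus(spec: LocusSpec):
    """Construct the reference contig, gene model and planted truth.

    Returns ``(reference_sequence, gene, truth)`` where the reference is a
    plain string.  The construction happens on the coding strand; for a minus
    strand spec the finished contig is reverse-complemented and every
    coordinate mirrored, so the recorded truth is always in plus-strand
    genomic coordinates while HGVS/PTC facts stay coding-strand quantities.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seq = _rand_seq(rng, spec.contig_length)

    # exon/intron layout on the coding strand
    exons: list[Interval] = []
    pos = spec.gene_offset
    for i, elen in enumerate(spec.exon_lengths):
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(spec.intron_lengths):
            pos += spec.intron_lengths[i]
    introns = [(a[1], b[0]) for a, b in zip(exons, exons[1:])]

    cds_start = exons[0][0] + spec.cds_start_exon_offset
    cds_end = exons[-1][0] + spec.cds_end_exon_offset
    if not exons[0][0] <= cds_start < exons[0][1]:
        raise ValueError("cds_start_exon_offset outside the first exon")
    if not exons[-1][0] < cds_end <= exons[-1][1]:
        raise ValueError("cds_end_exon_offset outside the last exon")

    coding_pos = np.concatenate(
        [np.arange(max(s, cds_start), min(e, cds_end)) for s, e in exons]
    )
    if len(coding_pos) % 3 != 0:
        raise ValueError(f"coding length {len(coding_pos)} is not a multiple of 3")

    # canonical ORF: ATG ... TAA with no internal stops
    seq[coding_pos[:3]] = np.frombuffer(b"ATG", dtype=np.uint8)
    seq[coding_pos[-3:]] = np.frombuffer(b"TAA", dtype=np.uint8)

    # canonical splice dinucleotides
    for s, e in introns:
        seq[s : s + 2] = np.frombuffer(b"GT", dtype=np.uint8)
        seq[e - 2 : e] = np.frombuffer(b"AG", dtype=np.uint8)

    # primer footprints written into the genome (forward into exon 2,
    # reverse-complemented reverse primer into the last exon)
    fwd, rev = DEFAULT_FORWARD_PRIMER, DEFAULT_REVERSE_PRIMER
    f_start = exons[1][0] + spec.forward_primer_exon_offset
    if f_start + len(fwd) > exons[1][1]:
        raise ValueError("forward primer footprint does not fit in exon 2")
    seq[f_start : f_start + len(fwd)] = np.frombuffer(fwd.encode(), dtype=np.uint8)
    rc_rev = revcomp(rev)
    r_start = exons[-1][0] + spec.reverse_primer_exon_offset
    if r_start + len(rc_rev) > exons[-1][1]:
        raise ValueError("reverse primer footprint does not fit in the last exon")
    seq[r_start : r_start + len(rc_rev)] = np.frombuffer(rc_rev.encode(), dtype=np.uint8)
    protected = set(range(f_start, f_start + len(fwd))) | set(
        range(r_start, r_start + len(rc_rev))
    )
    protected |= {int(i) for i in coding_pos[:3]} | {int(i) for i in coding_pos[-3:]}
    _scrub_stops(seq, coding_pos, protected)

    # haplotype B: scattered exonic substitutions inside the amplicon insert,
    # used to plant a second shared canonical amplicon allele
    hapb_positions: list[int] = []
    if spec.exon_count >= 4:
        for ex in (2, 3):  # 0-based exon indices 2 and 3 (exons 3 and 4)
            s, e = exons[ex]
            for off in (20, 45, 70, 95):
                p = s + off
                if p < e and p not in protected:
                    hapb_positions.append(p)
    hapb_positions = hapb_positions[:8]

    ce = spec.cryptic_exon
    ce_iv: Interval | None = None
    variant_pos0: int | None = None
    exon_alt_seq: str | None = None
    if ce is not None and ce.length > 0:
        istart, iend = introns[ce.intron_index - 1]
        ce_start = istart + ce.offset_into_intron
        ce_end = ce_start + ce.length
        ce_iv = (ce_start, ce_end)
        seq[ce_start - 2 : ce_start] = np.frombuffer(b"AG", dtype=np.uint8)
        seq[ce_end : ce_end + 2] = np.frombuffer(b"GT", dtype=np.uint8)

        # frame of the insertion point: coding bases upstream of this intron
        c_before = 0
        for s, e in exons[: ce.intron_index]:
            c_before += max(0, min(e, cds_end) - max(s, cds_start))
        phase = c_before % 3

        body = _rand_seq(rng, ce.length)
        upstream_tail = seq[coding_pos[c_before - phase : c_before]].tobytes().decode()

        def codon_at(j: int) -> tuple[str, list[int]]:
            """Codon j of the insertion frame: sequence and in-exon indices."""
            start = 3 * j - phase
            chars, idx = [], []
            for k in range(start, start + 3):
                if k < 0:
                    chars.append(upstream_tail[k + phase])
                elif k < ce.length:
                    chars.append(chr(body[k]))
                    idx.append(k)
                else:
                    chars.append("N")
            return "".join(chars), idx

        saa = ce.stop_after_aa
        if saa is not None:
            stop_begin = 3 * saa - phase
            if stop_begin < 0 or stop_begin + 3 > ce.length:
                raise ValueError(
                    "infeasible spec: planted stop codon does not fit inside the cryptic exon"
                )
            body[stop_begin : stop_begin + 3] = np.frombuffer(b"TGA", dtype=np.uint8)
            n_guard = saa
        else:
            n_guard = (ce.length + phase) // 3

        # variant codon: exon carries C at the variant site, genome carries G
        v0 = ce.variant_offset_in_exon - 1
        vj = (v0 + phase) // 3
        if saa is not None and vj >= saa:
            raise ValueError("infeasible spec: variant lies at or beyond the planted stop codon")
        _, vidx = codon_at(vj)
        for k in vidx:
            body[k] = ord("C")
        body[v0] = ord("C")

        # clear premature stops among the guarded codons
        for j in range(n_guard):
            codon, idx = codon_at(j)
            if codon in STOPS:
                if not idx:
                    raise ValueError("infeasible spec: upstream tail forms a stop codon")
                body[idx[-1]] = ord("C")
        # re-assert the variant base and the planted stop after scrubbing
        body[v0] = ord("C")
        if saa is not None:
            body[3 * saa - phase : 3 * saa - phase + 3] = np.frombuffer(b"TGA", dtype=np.uint8)
        # the reference (G) allele must not create a stop either
        body_ref = body.copy()
        body_ref[v0] = ord("G")
        alt_codon, _ = codon_at(vj)
        ref_codon = list(alt_codon)
        ref_codon[v0 - (3 * vj - phase)] = "G"  # v0's char index within its codon
        if "".join(ref_codon) in STOPS:
            raise ValueError("infeasible spec: reference allele at the variant site forms a stop")

        exon_alt_seq = body.tobytes().decode()
        seq[ce_start:ce_end] = body_ref
        variant_pos0 = ce_start + v0

        if spec.extended_acceptor_shift:
            ext_start = iend - spec.extended_acceptor_shift
            seq[ext_start - 2 : ext_start] = np.frombuffer(b"AG", dtype=np.uint8)

    contig = seq.tobytes().decode()
    gene = GeneModel(
        gene_name=spec.gene_name,
        transcript_label=spec.transcript_label,
        chrom=spec.contig_name,
        strand="+",
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )

    # isoform structures (coding-strand layout)
    structures: dict[str, list[Interval]] = {"canonical": list(exons)}
    if ce_iv is not None:
        i = ce.intron_index
        structures["cryptic"] = sorted(exons[:i] + [ce_iv] + exons[i:])
        if spec.extended_acceptor_shift:
            ext_exon = (exons[i][0] - spec.extended_acceptor_shift, exons[i][1])
            structures["cryptic_extended"] = sorted(
                exons[:i] + [ce_iv] + [ext_exon] + exons[i + 1 :]
            )

    # HGVS name from geometry (nearest-exon rule)
    hgvs = None
    if ce_iv is not None:
        ilen = spec.intron_lengths[ce.intron_index - 1]
        d_up = ce.offset_into_intron + ce.variant_offset_in_exon
        d_down = ilen - d_up + 1
        c_last = gene.cdna_coding_position(exons[ce.intron_index - 1][1] - 1)
        if d_up <= d_down:
            hgvs = f"c.{c_last}+{d_up}G>C"
        else:
            c_first = gene.cdna_coding_position(exons[ce.intron_index][0])
            hgvs = f"c.{c_first}-{d_down}G>C"

    canonical_mrna = gene.spliced_sequence(contig)
    cryptic_mrna = None
    if ce_iv is not None:
        m = list(gene.spliced_sequence(contig, structures["cryptic"]))
        m[gene.mrna_offset_of(variant_pos0, structures["cryptic"])] = "C"
        cryptic_mrna = "".join(m)

    if ce_iv is not None:
        iso_per_gt = {
            "homref": ["canonical"],
            "het": ["canonical"],
            "homalt": [k for k in structures],
        }
    else:
        iso_per_gt = {g: ["canonical"] for g in ("homref", "het", "homalt")}

    truth = PlantedTruth(
        contig_name=spec.contig_name,
        variant_position=(variant_pos0 + 1) if variant_pos0 is not None else 0,
        variant_ref="G",
        variant_alt="C",
        cryptic_exon_interval=ce_iv,
        expected_hgvs=hgvs,
        expected_ptc_aa=(ce.stop_after_aa if ce is not None and ce.length > 0 else None),
        isoform_set_per_genotype=iso_per_gt,
        isoform_structures=structures,
        canonical_mrna=canonical_mrna,
        cryptic_mrna=cryptic_mrna,
        haplotype_b_positions=hapb_positions,
    )

    if spec.strand == "-":
        contig, gene, truth = _mirror_locus(contig, gene, truth)
    return contig, gene, truth


def _mirror_locus(contig: str, gene: GeneModel, truth: PlantedTruth):
    """Reverse-complement the contig and mirror every genomic coordinate."""
    L = len(contig)
    flip = lambda iv: (L - iv[1], L - iv[0])
    contig2 = revcomp(contig)
    gene2 = GeneModel(
        gene.gene_name,
        gene.transcript_label,
        gene.chrom,
        "-",
        [flip(e) for e in gene.exons],
        L - gene.cds_end,
        L - gene.cds_start,
    )
    truth2 = dataclasses.replace(
        truth,
        variant_position=L - (truth.variant_position - 1),
        variant_ref=revcomp(truth.variant_ref),
        variant_alt=revcomp(truth.variant_alt),
        cryptic_exon_interval=(
            flip(truth.cryptic_exon_interval) if truth.cryptic_exon_interval else None
        ),
        isoform_structures={
            k: sorted(flip(iv) for iv in v) for k, v in truth.isoform_structures.items()
        },
        haplotype_b_positions=sorted(L - 1 - p for p in truth.haplotype_b_positions),
    )
    return contig2, gene2, truth2


# ---------------------------------------------------------------------------
# cohort genotypes and decoy variants


@dataclass
class SimVariant:
    """A site to place in the cohort VCF; ``alt_freq`` drives decoy draws."""

    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    effect: str
    impact: str
    causal: bool = False
    alt_freq: float = 0.0


def simulate_cohort_genotypes(design, variants, q_background: float, seed: int):
    """Draw per-sample genotypes for each variant.

    The causal variant segregates perfectly under the recessive model (cases
    1/1, obligate carriers 0/1, controls 0/0 or 0/1 at ``q_background`` with
    hom-alt redrawn); decoys are Hardy-Weinberg draws at their own
    ``alt_freq``.  Returns one {sample: genotype-word} map per variant.
    """
    if not 0 <= q_background <= 0.5:
        raise ValueError("q_background must be in [0, 0.5]")
    roles = design.roles if hasattr(design, "roles") else dict(design)
    samples = list(roles)
    if not any(r == "case" for r in roles.values()):
        raise ValueError("cohort has no cases")
    rng = np.random.default_rng(seed)
    out = []
    for v in variants:
        gts = {}
        for s in samples:
            role = roles[s]
            if v.causal:
                if role == "case":
                    gts[s] = "homalt"
                elif role == "obligate_carrier":
                    gts[s] = "het"
                elif role == "control":
                    gts[s] = "het" if rng.random() < 2 * q_background * (1 - q_background) else "homref"
                else:  # unknown: carrier parents in disguise
                    gts[s] = "het"
            else:
                q = v.alt_freq
                u = rng.random()
                if u < q * q:
                    gts[s] = "homalt"
                elif u < q * q + 2 * q * (1 - q):
                    gts[s] = "het"
                else:
                    gts[s] = "homref"
        out.append(gts)
    return out


def make_decoy_variants(
    region: Interval,
    n: int,
    seed: int,
    genes=("FADS6", "FDXR", "GRIN2C", "TMEM104"),
    freq_range=(0.05, 0.4),
    forbidden: set[int] | None = None,
) -> list[SimVariant]:
    """Non-causal background SNVs at recorded allele frequencies."""
    rng = np.random.default_rng(seed)
    lo, hi = region
    forbidden = forbidden or set()
    positions: set[int] = set()
    while len(positions) < n:
        p = int(rng.integers(lo, hi)) + 1
        if p not in forbidden:
            positions.add(p)
    bases = "ACGT"
    out = []
    for p in sorted(positions):
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        impact = str(rng.choice(["MODIFIER", "LOW", "MODERATE", "HIGH"], p=[0.7, 0.15, 0.1, 0.05]))
        effect = {
            "MODIFIER": "intron_variant",
            "LOW": "synonymous_variant",
            "MODERATE": "missense_variant",
            "HIGH": "stop_gained",
        }[impact]
        out.append(
            SimVariant(
                pos=p,
                ref=str(ref),
                alt=str(alt),
                gene=str(rng.choice(list(genes))),
                effect=effect,
                impact=impact,
                alt_freq=float(rng.uniform(*freq_range)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# spliced short-read block records


def simulate_spliced_reads(gene: GeneModel, isoforms, weights_per_sample, depth: int, seed: int):
    """Emit ``depth`` BED12-style block records per sample.

    ``isoforms`` maps isoform name -> block interval list; ``weights_per_sample``
    maps sample -> {isoform name: weight}.  Each read's blocks are exactly its
    source isoform's blocks.
    """
    from .cryptic import SplicedReadBlocks

    rng = np.random.default_rng(seed)
    out = []
    for sample in weights_per_sample:
        weights = weights_per_sample[sample]
        if not weights:
            raise ValueError(f"sample {sample} has no isoform weights")
        names = sorted(weights)
        w = np.array([weights[n] for n in names], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("isoform weights must be nonnegative with positive sum")
        w = w / w.sum()
        picks = rng.choice(len(names), size=depth, p=w)
        for k in picks:
            name = names[int(k)]
            out.append(
                SplicedReadBlocks(
                    sample=sample,
                    blocks=sorted(isoforms[name]),
                    isoform_tag=name,
                    chrom=gene.chrom,
                    strand=gene.strand,
                )
            )
    return out


# ---------------------------------------------------------------------------
# long-read amplicons


def simulate_amplicon_reads(
    inserts: dict[str, str],
    per_sample_mixture: dict[str, dict[str, float]],
    primers,
    error_rate: float = 0.01,
    n_reads: int = 1000,
    seed: int = 0,
    corrupted_primer_fraction: float = 0.0,
):
    """FASTQ-style amplicon reads: F + insert + rc(R) with i.i.d. substitutions.

    A ``corrupted_primer_fraction`` of reads has one forward-primer base
    flipped (beyond the background error process) so exact-primer trimming
    rejection is exercised; roughly half the reads are emitted in reverse
    orientation.  The sample of origin is recorded in the read id.
    """
    from .amplicon import AmpliconRead

    if error_rate >= 0.02:
        raise ValueError("error_rate must be < 0.02")
    rng = np.random.default_rng(seed)
    fwd = primers.forward
    rc_rev = revcomp(primers.reverse)
    reads = []
    for sample in per_sample_mixture:
        mix = per_sample_mixture[sample]
        if not mix:
            raise ValueError(f"sample {sample} has an empty isoform mixture")
        names = sorted(mix)
        w = np.array([mix[n] for n in names], dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        picks = rng.choice(len(names), size=n_reads, p=w)
        for i, k in enumerate(picks):
            amplicon = fwd + inserts[names[int(k)]] + rc_rev
            arr = np.frombuffer(amplicon.encode(), dtype=np.uint8).copy()
            nerr = rng.binomial(len(arr), error_rate)
            if nerr:
                idx = rng.choice(len(arr), size=nerr, replace=False)
                shift = rng.integers(1, 4, size=nerr)
                lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
                for p, sh in zip(idx, shift):
                    arr[p] = ord(lut[int(arr[p])][int(sh) - 1])
            if rng.random() < corrupted_primer_fraction:
                p = int(rng.integers(0, len(fwd)))
                arr[p] = ord({65: "C", 67: "A", 71: "T", 84: "G"}[int(arr[p])])
            seq = arr.tobytes().decode()
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(
                AmpliconRead(
                    id=f"{sample}:{i:06d}", sample=sample, sequence=seq, mean_quality=30.0
                )
            )
    return reads


def amplicon_inserts(contig: str, gene: GeneModel, truth: PlantedTruth, primers) -> dict[str, str]:
    """Trimmed insert sequences (between the primers) for every planted isoform.

    Returns canonical haplotypes A and B plus the cryptic isoforms on the A
    background; cryptic inserts carry the alternate (C) allele at the planted
    variant site, as transcribed from the disease haplotype.
    """
    fwd, rc_rev = primers.forward, revcomp(primers.reverse)
    out = {}
    for name, blocks in truth.isoform_structures.items():
        mrna = gene.spliced_sequence(contig, blocks)
        if name.startswith("cryptic"):
            # the disease haplotype transcribes the alternate allele, which is
            # always C on the coding strand
            off = gene.mrna_offset_of(truth.variant_position - 1, blocks)
            mrna = mrna[:off] + "C" + mrna[off + 1 :]
        fi = mrna.find(fwd)
        ri = mrna.find(rc_rev)
        if fi < 0 or ri < 0 or ri <= fi:
            raise ValueError(f"primers do not flank isoform {name}")
        key = "canonical_A" if name == "canonical" else name
        out[key] = mrna[fi + len(fwd) : ri]
    # haplotype B: mirror of canonical_A with the planted substitutions
    if truth.haplotype_b_positions:
        blocks = truth.isoform_structures["canonical"]
        mrna = gene.spliced_sequence(contig, blocks)
        m = list(mrna)
        flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for p in truth.haplotype_b_positions:
            off = gene.mrna_offset_of(p, blocks)
            m[off] = flip[m[off]]
        mrna_b = "".join(m)
        fi = mrna_b.find(fwd)
        ri = mrna_b.find(rc_rev)
        out["canonical_B"] = mrna_b[fi + len(fwd) : ri]
    return out


# ---------------------------------------------------------------------------
# genotyping panel


def simulate_panel(n: int, q: float, seed: int, exclude_homalt: bool = True):
    """Hardy-Weinberg genotype counts for a carrier-screening panel.

    With ``exclude_homalt`` (rare-disease ascertainment: affected homozygotes
    do not reach the screening panel) hom-alt draws are redrawn.
    """
    from .popgen import GenotypeCounts

    if n < 1:
        raise ValueError("panel size must be >= 1")
    rng = np.random.default_rng(seed)
    p_hom = q * q
    p_het = 2 * q * (1 - q)
    u = rng.random(n)
    hom = u < p_hom
    het = (u >= p_hom) & (u < p_hom + p_het)
    if exclude_homalt and q < 1.0:
        while hom.any():
            redraws = rng.random(int(hom.sum()))
            new_hom = redraws < p_hom
            new_het = (redraws >= p_hom) & (redraws < p_hom + p_het)
            idx = np.flatnonzero(hom)
            het[idx[new_het]] = True
            hom[idx] = False
            hom[idx[new_hom]] = True
    return GenotypeCounts(n_het=int(het.sum()), n_homalt=int(hom.sum()), n_total=n)
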