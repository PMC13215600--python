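"""Recessive-model variant prioritisation over a cohort VCF.

Implements the filter chain used to nominate candidate variants for an
autosomal recessive disease: per-sample segregation predicates (cases
homozygous-alternate, obligate carriers heterozygous, no homozygous-alternate
control), a two-sided allelic Fisher exact test on case/control allele
counts, SnpEff impact screening, cross-population exclusion against variants
observed in other breeds, candidate-region definition and HGVS intronic
naming of deep-intronic variants.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path

from scipy.stats import hypergeom

from .genemodel import GeneModel

IMPACTS = {"HIGH", "MODERATE", "LOW", "MODIFIER"}
GENOTYPES = {"homref", "het", "homalt", "missing"}


class VcfParseError(ValueError):
    pass


@dataclass
class VariantAnnotation:
    gene: str
    effect: str
    impact: str
    allele: str = ""

    def __post_init__(self):
        if self.impact not in IMPACTS:
            raise ValueError(f"unknown impact class {self.impact!r}")


@dataclass
class VariantRecord:
    """One VCF site (one alternate allele) with per-sample genotype words."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, str] = field(default_factory=dict)
    annotations: list[VariantAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.alt)


@dataclass
class CohortDesign:
    """sample -> role map; roles drive every segregation predicate."""

    roles: dict[str, str]

    def __post_init__(self):
        allowed = {"case", "obligate_carrier", "control", "unknown"}
        bad = {r for r in self.roles.values() if r not in allowed}
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        if "case" not in self.roles.values():
            raise ValueError("cohort design must contain at least one case")

    def samples_with(self, role: str) -> list[str]:
        return [s for s, r in self.roles.items() if r == role]

    @property
    def cases(self):
        return self.samples_with("case")

    @property
    def carriers(self):
        return self.samples_with("obligate_carrier")

    @property
    def controls(self):
        return self.samples_with("control")


@dataclass
class AssociationResult:
    variant: VariantRecord
    p_allelic: float
    allele_counts: tuple[int, int, int, int]  # case_alt, case_ref, ctrl_alt, ctrl_ref


@dataclass
class CandidateRegion:
    chrom: str
    start: int  # 1-based
    end: int
    span: int
    n_variants: int


@dataclass
class HgvsIntronicName:
    transcript_label: str
    anchor_cdna_pos: int
    offset: int  # signed: + anchored upstream, - anchored downstream
    ref: str
    alt: str
    rendered: str


# ---------------------------------------------------------------------------
# parsing


def parse_ann(info_field: str) -> list[VariantAnnotation]:
    """Parse a SnpEff-style ANN value: 'Allele|Effect|Impact|Gene[,...]'."""
    if not info_field:
        return []
    out = []
    for entry in info_field.split(","):
        parts = entry.split("|")
        if len(parts) < 4:
            raise ValueError(f"ANN entry needs Allele|Effect|Impact|Gene, got {entry!r}")
        allele, effect, impact, gene = parts[0], parts[1], parts[2], parts[3]
        out.append(VariantAnnotation(gene=gene, effect=effect, impact=impact, allele=allele))
    return out


def _gt_word(gt: str, alt_index: int) -> str:
    alleles = gt.replace("|", "/").split("/")
    if "." in alleles:
        return "missing"
    n = sum(1 for a in alleles if a == str(alt_index))
    return {2: "homalt", 1: "het", 0: "homref"}[min(n, 2)]


def parse_vcf(source) -> list[VariantRecord]:
    """Parse a VCF 4.2 text (path, file-like, or string) into variant records.

    Multiallelic sites are split into one record per alternate allele, with
    genotypes recoded against that allele; missing genotypes are preserved.
    Malformed rows raise :class:`VcfParseError` naming the line number.
    """
    if hasattr(source, "read"):
        fh = source
    elif isinstance(source, str) and "\n" in source:
        fh = _io.StringIO(source)
    else:
        fh = open(Path(source))
    samples: list[str] | None = None
    records: list[VariantRecord] = []
    try:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT":
                    raise VcfParseError(f"line {n}: malformed #CHROM header")
                samples = cols[9:]
                continue
            if samples is None:
                raise VcfParseError(f"line {n}: data row before #CHROM header")
            f = line.split("\t")
            if len(f) != 9 + len(samples):
                raise VcfParseError(
                    f"line {n}: expected {9 + len(samples)} columns, got {len(f)}"
                )
            chrom, pos_s, _, ref, alt_s, _, _, info, fmt = f[:9]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfParseError(f"line {n}: non-integer POS {pos_s!r}") from None
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise VcfParseError(f"line {n}: FORMAT lacks GT")
            gt_i = fmt_keys.index("GT")
            ann_value = ""
            for kv in info.split(";"):
                if kv.startswith("ANN="):
                    ann_value = kv[4:]
            try:
                annotations = parse_ann(ann_value)
            except ValueError as e:
                raise VcfParseError(f"line {n}: {e}") from None
            alts = alt_s.split(",")
            for ai, alt in enumerate(alts, start=1):
                gts = {}
                for s, cell in zip(samples, f[9:]):
                    gt = cell.split(":")[gt_i]
                    try:
                        gts[s] = _gt_word(gt, ai)
                    except (KeyError, ValueError):
                        raise VcfParseError(f"line {n}: malformed genotype {gt!r}") from None
                anns = [a for a in annotations if a.allele in ("", alt)]
                records.append(
                    VariantRecord(
                        chrom=chrom, pos=pos, ref=ref, alt=alt,
                        genotypes=gts, annotations=anns,
                    )
                )
    finally:
        if fh is not source and not isinstance(fh, _io.StringIO):
            fh.close()
    return records


# ---------------------------------------------------------------------------
# allelic exact test


def allelic_fisher(case_alt: int, case_ref: int, ctrl_alt: int, ctrl_ref: int) -> float:
    """Two-sided Fisher exact p for the 2x2 allele-count table.

    Sums hypergeometric probabilities (margins fixed) of every table at most
    as probable as the observed one, with a 1e-12 relative tolerance for
    ties.  An all-zero table returns 1 by convention.
    """
    if min(case_alt, case_ref, ctrl_alt, ctrl_ref) < 0:
        raise ValueError("counts must be nonnegative")
    n_case = case_alt + case_ref
    n_alt = case_alt + ctrl_alt
    total = n_case + ctrl_alt + ctrl_ref
    if total == 0:
        return 1.0
    rv = hypergeom(total, n_alt, n_case)
    lo = max(0, n_case + n_alt - total)
    hi = min(n_case, n_alt)
    support = range(lo, hi + 1)
    p_obs = rv.pmf(case_alt)
    p = sum(pk for k in support if (pk := rv.pmf(k)) <= p_obs * (1 + 1e-12))
    return min(1.0, float(p))


def allele_counts(variant: VariantRecord, design: CohortDesign) -> tuple[int, int, int, int]:
    """Case/control alt and ref allele counts; missing genotypes excluded."""
    w = {"homalt": (2, 0), "het": (1, 1), "homref": (0, 2)}
    ca = cr = ta = tr = 0
    for s in design.cases:
        g = variant.genotypes.get(s, "missing")
        if g != "missing":
            ca += w[g][0]
            cr += w[g][1]
    for s in design.controls:
        g = variant.genotypes.get(s, "missing")
        if g != "missing":
            ta += w[g][0]
            tr += w[g][1]
    return ca, cr, ta, tr


def associate(variant: VariantRecord, design: CohortDesign) -> AssociationResult:
    counts = allele_counts(variant, design)
    return AssociationResult(variant, allelic_fisher(*counts), counts)


# ---------------------------------------------------------------------------
# filters


def recessive_segregation_filter(variants, design: CohortDesign, allow_missing: bool = False):
    """Keep variants segregating perfectly under the recessive model.

    Every case must be hom-alt, every obligate carrier het, and no control
    hom-alt; a missing genotype fails the predicate unless ``allow_missing``.
    Samples with role ``unknown`` are ignored.
    """

    def ok(v: VariantRecord) -> bool:
        for s in design.cases:
            g = v.genotypes.get(s, "missing")
            if g == "missing":
                if not allow_missing:
                    return False
            elif g != "homalt":
                return False
        for s in design.carriers:
            g = v.genotypes.get(s, "missing")
            if g == "missing":
                if not allow_missing:
                    return False
            elif g != "het":
                return False
        for s in design.controls:
            g = v.genotypes.get(s, "missing")
            if g == "missing":
                if not allow_missing:
                    return False
            elif g == "homalt":
                return False
        return True

    return [v for v in variants if ok(v)]


def impact_filter(variants, allowed) -> list:
    """Keep variants with at least one annotation whose impact is allowed."""
    allowed = set(allowed)
    bad = allowed - IMPACTS
    if bad:
        raise ValueError(f"unknown impact classes: {bad}")
    return [v for v in variants if any(a.impact in allowed for a in v.annotations)]


def cross_population_exclude(variants, external_observations, home_breed: str) -> list:
    """Drop variants whose (chrom, pos, alt) was seen in any other breed."""
    out = []
    for v in variants:
        breeds = external_observations.get(v.key, set())
        if not (set(breeds) - {home_breed}):
            out.append(v)
    return out


def define_candidate_region(variants) -> CandidateRegion:
    """Interval bounded by the outermost variants (single chromosome)."""
    if not variants:
        raise ValueError("no variants to define a region from")
    chroms = {v.chrom for v in variants}
    if len(chroms) > 1:
        raise ValueError(f"variants span multiple chromosomes: {sorted(chroms)}")
    pos = [v.pos for v in variants]
    start, end = min(pos), max(pos)
    return CandidateRegion(
        chrom=variants[0].chrom, start=start, end=end, span=end - start,
        n_variants=len(variants),
    )


def candidate_filter_chain(
    variants,
    design: CohortDesign,
    p_threshold: float = 1e-11,
    impacts=None,
    observations=None,
    home_breed: str = "Quarter Horse",
    allow_missing: bool = False,
):
    """The full prioritisation flow: segregation, association, optional
    impact screen, cross-population exclusion.  Returns (kept variants,
    {key: AssociationResult})."""
    kept = recessive_segregation_filter(variants, design, allow_missing=allow_missing)
    assoc = {v.key: associate(v, design) for v in kept}
    kept = [v for v in kept if assoc[v.key].p_allelic < p_threshold]
    if impacts is not None:
        kept = impact_filter(kept, impacts)
    if observations is not None:
        kept = cross_population_exclude(kept, observations, home_breed)
    return kept, assoc


# ---------------------------------------------------------------------------
# HGVS intronic naming


def hgvs_intronic_name(
    variant: VariantRecord, gene: GeneModel, transcript_label: str | None = None
) -> HgvsIntronicName:
    """Name an intronic variant with nearest-exon c.X+Y / c.X-Y notation.

    The anchor is the cDNA coding coordinate of the flanking exonic base on
    the nearer side ('+' anchored to the upstream exon's last coding base
    when it is nearer or equidistant); alleles are reported on the coding
    strand.
    """
    g = variant.pos - 1
    if gene.is_exonic(g):
        raise ValueError(
            "position is exonic; use exonic HGVS nomenclature (not handled here)"
        )
    idx = gene.intron_index_of(g)
    if idx is None:
        raise ValueError("position lies outside the transcript's introns")
    up = gene.exons_tx_order()[idx - 1]
    down = gene.exons_tx_order()[idx]
    if gene.strand == "+":
        d_up = g - (up[1] - 1)
        d_down = down[0] - g
        ref, alt = variant.ref, variant.alt
    else:
        from .genemodel import revcomp

        d_up = up[0] - g
        d_down = g - (down[1] - 1)
        ref, alt = revcomp(variant.ref), revcomp(variant.alt)
    label = transcript_label or gene.transcript_label
    if d_up <= d_down:
        anchor_g = up[1] - 1 if gene.strand == "+" else up[0]
        anchor = gene.cdna_coding_position(anchor_g)
        rendered = f"c.{anchor}+{d_up}{ref}>{alt}"
        return HgvsIntronicName(label, anchor, d_up, ref, alt, rendered)
    anchor_g = down[0] if gene.strand == "+" else down[1] - 1
    anchor = gene.cdna_coding_position(anchor_g)
    rendered = f"c.{anchor}-{d_down}{ref}>{alt}"
    return HgvsIntronicName(label, anchor, -d_down, ref, alt, rendered)
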