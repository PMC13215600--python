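"""Long-read amplicon isoform analysis.

Re-implements the nanopore amplicon chain: per-sample subsampling, exact
primer trimming (inexact matches rejected), greedy centroid clustering at a
global-identity threshold, the per-sample >10% significance rule, majority
consensus over a subsample of members, case/control cluster classification,
and mapping of consensus sequences back to the gene to recover exon
structures, novel (cryptic) blocks and extended exon boundaries.

Identity is defined on the optimal global alignment under match +1,
mismatch -1, gap -2, counting identical columns over all columns (gap
columns count against identity).  ``global_identity`` computes exactly that
DP; the clustering loop uses a vectorised Hamming fast path for equal-length
sequences (for which the gapless alignment is score-optimal on
substitution-dominated data) plus the rigorous length-ratio upper bound
identity <= min(len)/max(len) to skip hopeless comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .genemodel import GeneModel, Interval, revcomp


@dataclass
class AmpliconRead:
    id: str
    sample: str
    sequence: str
    mean_quality: float | None = None


@dataclass
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self):
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError("primers must be >= 15 bp")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


@dataclass
class Cluster:
    id: int
    centroid_read: str  # read id
    member_ids: list[str] = field(default_factory=list)
    per_sample_counts: dict[str, int] = field(default_factory=dict)
    mean_length: float = 0.0

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ConsensusSequence:
    cluster_id: int
    sequence: str
    support_per_column: list[float] = field(default_factory=list)


@dataclass
class IsoformStructure:
    """Consensus decomposed onto the genome (plus-strand 0-based intervals)."""

    exon_intervals: list[Interval] = field(default_factory=list)
    novel_blocks: list[Interval] = field(default_factory=list)
    extended_boundaries: list[tuple[int, int]] = field(default_factory=list)

    @property
    def all_blocks(self) -> list[Interval]:
        return sorted(self.exon_intervals + self.novel_blocks)


# ---------------------------------------------------------------------------
# read preparation


def quality_filter(reads, min_mean_quality: float = 10.0):
    """Drop reads whose mean phred quality is below threshold (no-op when absent)."""
    return [r for r in reads if r.mean_quality is None or r.mean_quality >= min_mean_quality]


def subsample_reads(reads, n: int, seed: int):
    """Uniform per-sample subsample without replacement, original order kept."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    by_sample: dict[str, list] = {}
    for r in reads:
        by_sample.setdefault(r.sample, []).append(r)
    out = []
    for sample in by_sample:
        grp = by_sample[sample]
        if len(grp) <= n:
            out.extend(grp)
        else:
            idx = np.sort(rng.choice(len(grp), size=n, replace=False))
            out.extend(grp[int(i)] for i in idx)
    return out


REJECT_NO_FORWARD = "no_exact_forward_primer"
REJECT_NO_REVERSE = "no_exact_reverse_primer"


def trim_primers(read: AmpliconRead, primers: PrimerPair):
    """Exact primer trimming; returns ``(insert, None)`` or ``(None, reason)``.

    The forward primer must sit exactly at the 5' end and the
    reverse-complemented reverse primer exactly at the 3' end, in either
    read orientation; the insert is returned in forward orientation.
    """
    rc_rev = revcomp(primers.reverse)
    for seq in (read.sequence, revcomp(read.sequence)):
        if seq.startswith(primers.forward):
            if seq.endswith(rc_rev):
                return seq[len(primers.forward) : len(seq) - len(rc_rev)], None
            return None, REJECT_NO_REVERSE
    return None, REJECT_NO_FORWARD


def trim_all(reads, primers: PrimerPair):
    """Trim every read; returns (trimmed reads, per-sample rejection tallies)."""
    trimmed, rejected = [], {}
    for r in reads:
        insert, reason = trim_primers(r, primers)
        if insert is None:
            rejected.setdefault(r.sample, {}).setdefault(reason, 0)
            rejected[r.sample][reason] += 1
        else:
            trimmed.append(
                AmpliconRead(id=r.id, sample=r.sample, sequence=insert,
                             mean_quality=r.mean_quality)
            )
    return trimmed, rejected


# ---------------------------------------------------------------------------
# identity and clustering


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


_ALIGNER = _aligner()


def global_identity(a: str, b: str) -> float:
    """Identical columns / total columns of the optimal global alignment."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total


def greedy_cluster(reads, threshold: float = 0.98, identity_fn=None) -> list[Cluster]:
    """Greedy centroid clustering at a global-identity threshold.

    Reads are processed sorted by length descending (ties by id ascending);
    each read joins the earliest-created cluster whose centroid identity is
    >= threshold, otherwise founds a new cluster with itself as centroid.
    ``identity_fn`` overrides the identity computation (used by oracle
    tests); by default the exact-DP identity is accelerated as described in
    the module docstring.
    """
    if not reads:
        raise ValueError("no reads to cluster")
    order = sorted(reads, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[Cluster] = []
    centroid_seq: list[str] = []
    # per-length fast-path state: length -> (cluster indices, stacked uint8 matrix)
    groups: dict[int, list[int]] = {}
    arrays: dict[int, np.ndarray] = {}

    def encode(s: str) -> np.ndarray:
        return np.frombuffer(s.encode(), dtype=np.uint8)

    for r in order:
        seq = r.sequence
        L = len(seq)
        best = None
        if identity_fn is not None:
            for ci, cs in enumerate(centroid_seq):
                if identity_fn(seq, cs) >= threshold:
                    best = ci
                    break
        else:
            candidates = []
            if L in groups and len(groups[L]):
                arr = encode(seq)
                mat = arrays[L][: len(groups[L])]
                dist = (mat != arr).sum(axis=1)
                ok = np.flatnonzero((L - dist) / L >= threshold)
                if ok.size:
                    candidates.append(min(groups[L][int(i)] for i in ok))
            for Lc, idxs in groups.items():
                if Lc == L:
                    continue
                if min(L, Lc) / max(L, Lc) < threshold:
                    continue  # identity upper bound already below threshold
                for ci in idxs:
                    if global_identity(seq, centroid_seq[ci]) >= threshold:
                        candidates.append(ci)
                        break
            best = min(candidates) if candidates else None
        if best is None:
            ci = len(clusters)
            clusters.append(Cluster(id=ci, centroid_read=r.id))
            centroid_seq.append(seq)
            if identity_fn is None:
                idxs = groups.setdefault(L, [])
                if L not in arrays:
                    arrays[L] = np.empty((16, L), dtype=np.uint8)
                elif len(idxs) == arrays[L].shape[0]:
                    arrays[L] = np.vstack([arrays[L], np.empty_like(arrays[L])])
                arrays[L][len(idxs)] = encode(seq)
                idxs.append(ci)
            best = ci
        c = clusters[best]
        c.member_ids.append(r.id)
        c.per_sample_counts[r.sample] = c.per_sample_counts.get(r.sample, 0) + 1
        c.mean_length += L  # running sum; divided below
    for c in clusters:
        c.mean_length = c.mean_length / c.size
    return clusters


def significant_clusters(clusters, per_sample_totals, fraction: float = 0.10):
    """Clusters holding strictly more than ``fraction`` of some sample's reads."""
    out = []
    for c in clusters:
        for s, total in per_sample_totals.items():
            if total <= 0:
                continue  # zero-total samples are excluded from the rule
            if c.per_sample_counts.get(s, 0) / total > fraction:
                out.append(c)
                break
    return out


# ---------------------------------------------------------------------------
# consensus


def consensus(cluster: Cluster, reads_by_id, k: int = 25, seed: int = 0) -> ConsensusSequence:
    """Majority consensus over a random subsample of cluster members.

    Members are laid out in a star multiple alignment anchored on the
    cluster centroid (each member pairwise-aligned to it); per column the
    majority symbol wins, ties are broken by the centroid's symbol, and
    columns whose most common symbol is a gap are deleted.
    """
    if not cluster.member_ids:
        raise ValueError("empty cluster")
    rng = np.random.default_rng(seed)
    members = cluster.member_ids
    if len(members) > k:
        idx = np.sort(rng.choice(len(members), size=k, replace=False))
        members = [members[int(i)] for i in idx]
    centroid = reads_by_id[cluster.centroid_read].sequence
    n = len(centroid)
    # columns anchored at centroid positions; insertion columns keyed
    # (position, rank) sort between anchors
    col_syms: dict[tuple[int, int], list[str]] = {(i, 0): [] for i in range(n)}
    for mid in members:
        seq = reads_by_id[mid].sequence
        if seq == centroid:
            for i, ch in enumerate(seq):
                col_syms[(i, 0)].append(ch)
            continue
        aln = _ALIGNER.align(centroid, seq)[0]
        ins_rank: dict[int, int] = {}
        ci = mi = 0
        for (c0, c1), (m0, m1) in zip(aln.aligned[0], aln.aligned[1]):
            # gap in member over centroid positions ci..c0
            while ci < c0:
                col_syms[(ci, 0)].append("-")
                ci += 1
            # insertion in member before centroid position c0
            while mi < m0:
                r = ins_rank.get(c0, 0) + 1
                ins_rank[c0] = r
                col_syms.setdefault((c0 - 1, r) if c0 > 0 else (-1, r), []).append(seq[mi])
                mi += 1
            for off in range(c1 - c0):
                col_syms[(c0 + off, 0)].append(seq[m0 + off])
            ci, mi = c1, m1
        while ci < n:
            col_syms[(ci, 0)].append("-")
            ci += 1
    out_chars, support = [], []
    n_members = len(members)
    for key in sorted(col_syms):
        syms = col_syms[key]
        if not syms:
            continue
        counts: dict[str, int] = {}
        for ch in syms:
            counts[ch] = counts.get(ch, 0) + 1
        counts["-"] = counts.get("-", 0) + (n_members - len(syms))  # absent = gap
        top = max(counts.values())
        tied = sorted(ch for ch, c in counts.items() if c == top)
        centroid_sym = centroid[key[0]] if key[1] == 0 and key[0] >= 0 else "-"
        pick = centroid_sym if centroid_sym in tied else tied[0] if tied != ["-"] else "-"
        if len(tied) == 1:
            pick = tied[0]
        if pick == "-":
            continue
        out_chars.append(pick)
        support.append(counts[pick] / n_members)
    return ConsensusSequence(cluster.id, "".join(out_chars), support)


# ---------------------------------------------------------------------------
# classification


def classify_clusters(clusters, design, min_reads: int = 5) -> dict[int, str]:
    """Label clusters shared / case_only / control_only by per-sample depth."""
    cases = design.cases
    controls = design.controls
    if not controls:
        warnings.warn("no control samples: every cluster will look case-only")
    out = {}
    for c in clusters:
        cnt = c.per_sample_counts
        case_hit = any(cnt.get(s, 0) >= min_reads for s in cases)
        ctrl_hit = any(cnt.get(s, 0) >= min_reads for s in controls)
        ctrl_all_low = all(cnt.get(s, 0) < min_reads for s in controls)
        case_all_low = all(cnt.get(s, 0) < min_reads for s in cases)
        if case_hit and ctrl_all_low:
            out[c.id] = "case_only"
        elif ctrl_hit and case_all_low:
            out[c.id] = "control_only"
        else:
            out[c.id] = "shared"
    return out


# ---------------------------------------------------------------------------
# mapping consensus sequences back to the gene

_SEED_LEN = 20
_CONFIRM = 10
_MAX_MISMATCH_PER_BLOCK = 2


def _extend_right(c: str, G: str, ci: int, gi: int, budget: int) -> tuple[int, int]:
    """Extend a match rightwards from (ci, gi); returns (span, mismatches used).

    A mismatch is bridged only when the following bases (10, or all that
    remain before the sequence edge) match exactly, so splice junctions stay
    boundary-exact; the returned span always ends on a match.
    """
    t = m = last = 0
    while ci + t < len(c) and gi + t < len(G):
        if c[ci + t] == G[gi + t]:
            t += 1
            last = t
            continue
        w = min(_CONFIRM, len(c) - (ci + t + 1), len(G) - (gi + t + 1))
        if m < budget and c[ci + t + 1 : ci + t + 1 + w] == G[gi + t + 1 : gi + t + 1 + w]:
            m += 1
            t += 1
            continue
        break
    return last, m


def _extend_left(c: str, G: str, ci: int, gi: int, cmin: int, gmin: int,
                 budget: int) -> tuple[int, int]:
    """Mirror of :func:`_extend_right` toward smaller indices."""
    t = m = last = 0
    while ci - t - 1 >= cmin and gi - t - 1 >= gmin:
        if c[ci - t - 1] == G[gi - t - 1]:
            t += 1
            last = t
            continue
        w = min(_CONFIRM, (ci - t - 1) - cmin, (gi - t - 1) - gmin)
        if m < budget and c[ci - t - 1 - w : ci - t - 1] == G[gi - t - 1 - w : gi - t - 1]:
            m += 1
            t += 1
            continue
        break
    return last, m


def _snap_junctions(blocks: list[Interval], G: str, max_shift: int = 10) -> list[Interval]:
    """Resolve junction boundary ambiguity toward canonical splice motifs.

    When the same consensus bases match the genome on both sides of a
    junction, the split between two adjacent blocks can slide; among the
    sequence-consistent shifts the one placing GT right after the donor and
    AG right before the acceptor is chosen (smallest shift wins ties).
    ``blocks`` and ``G`` are in coding orientation, so the donor side of a
    junction is always the left block's end.
    """
    blocks = [list(b) for b in blocks]
    for k in range(len(blocks) - 1):
        b1, b2 = blocks[k], blocks[k + 1]
        if b2[0] - b1[1] < 2:
            continue  # no intron between the blocks

        def consistent(s: int) -> bool:
            if s == 0:
                return True
            if s < 0:  # move |s| bases from the donor block to the acceptor block
                return (
                    b1[1] + s > b1[0]
                    and G[b1[1] + s : b1[1]] == G[b2[0] + s : b2[0]]
                )
            return b2[0] + s < b2[1] and G[b1[1] : b1[1] + s] == G[b2[0] : b2[0] + s]

        def motif(s: int) -> bool:
            d, a = b1[1] + s, b2[0] + s
            return G[d : d + 2] == "GT" and G[a - 2 : a] == "AG"

        if motif(0):
            continue
        for s in sorted(range(-max_shift, max_shift + 1), key=abs):
            if s and consistent(s) and motif(s):
                b1[1] += s
                b2[0] += s
                break
    return [tuple(b) for b in blocks]


def map_consensus(consensus_seq: str, reference: str, gene: GeneModel) -> IsoformStructure:
    """Decompose a consensus into ordered genomic blocks and label them.

    Blocks are maximal near-exact matches (<=2 isolated mismatches each,
    a mismatch being bridged only when the following 10 bases match
    exactly, which keeps splice boundaries exact) against the gene's
    genomic span in coding orientation.  Blocks coinciding with annotated
    exons are canonical; intronic blocks are novel; a canonical match
    running past an annotated exon edge is reported as an extended
    boundary.
    """
    if len(consensus_seq) < 50:
        raise ValueError("consensus too short to map (need >= 50 bp)")
    span_s, span_e = gene.span
    G = reference[span_s:span_e]
    if gene.strand == "-":
        G = revcomp(G)
    c = consensus_seq.upper()
    blocks_local: list[Interval] = []
    placed = 0
    i = 0
    g_min = 0
    while i <= len(c) - _SEED_LEN:
        anchor = None
        for s_off in range(0, len(c) - _SEED_LEN - i + 1):
            j = G.find(c[i + s_off : i + s_off + _SEED_LEN], g_min + s_off)
            if j >= 0:
                anchor = (i + s_off, j)
                break
        if anchor is None:
            break
        cs, gs = anchor
        lt, used = _extend_left(c, G, cs, gs, cmin=i, gmin=g_min,
                                budget=_MAX_MISMATCH_PER_BLOCK)
        rt, _ = _extend_right(c, G, cs + _SEED_LEN, gs + _SEED_LEN,
                              budget=_MAX_MISMATCH_PER_BLOCK - used)
        start_g, end_g = gs - lt, gs + _SEED_LEN + rt
        blocks_local.append((start_g, end_g))
        placed += end_g - start_g
        g_min = end_g
        i = cs + _SEED_LEN + rt
    blocks_local = _snap_junctions(blocks_local, G)
    if placed < 0.8 * len(c):
        raise ValueError(
            f"consensus unmappable: only {placed}/{len(c)} bases placed on the gene span"
        )
    # convert to plus-strand genomic coordinates
    def to_genomic(iv: Interval) -> Interval:
        if gene.strand == "+":
            return (span_s + iv[0], span_s + iv[1])
        return (span_e - iv[1], span_e - iv[0])

    genomic = sorted(to_genomic(b) for b in blocks_local)
    structure = IsoformStructure()
    exons_tx = gene.exons_tx_order()
    for b in genomic:
        overlaps = [
            (k, ex)
            for k, ex in enumerate(exons_tx, start=1)
            if b[0] < ex[1] and ex[0] < b[1]
        ]
        if not overlaps:
            structure.novel_blocks.append(b)
            continue
        structure.exon_intervals.append(b)
        for k, ex in overlaps:
            left = ex[0] - b[0]  # genomic-left overhang
            right = b[1] - ex[1]
            if gene.strand == "+":
                for shift in (left, right):
                    if shift > 0:
                        structure.extended_boundaries.append((k, shift))
            else:
                for shift in (right, left):
                    if shift > 0:
                        structure.extended_boundaries.append((k, shift))
    structure.exon_intervals.sort()
    structure.novel_blocks.sort()
    return structure


def primer_footprints(reference: str, gene: GeneModel, primers: PrimerPair):
    """Genomic intervals where the primers sit on the transcript."""
    span_s, span_e = gene.span
    G = reference[span_s:span_e]
    if gene.strand == "-":
        G = revcomp(G)
    f = G.find(primers.forward)
    r = G.find(revcomp(primers.reverse))
    if f < 0 or r < 0:
        raise ValueError("primer sequences not found on the coding strand of the gene span")

    def to_genomic(s, e):
        if gene.strand == "+":
            return (span_s + s, span_s + e)
        return (span_e - e, span_e - s)

    return (
        to_genomic(f, f + len(primers.forward)),
        to_genomic(r, r + len(primers.reverse)),
    )


def predict_amplicon_lengths(
    isoforms, footprints, include_primers: bool = False
) -> list[int]:
    """Per-isoform amplicon insert length between the primer footprints.

    By default primer footprints are excluded, matching trimmed-read cluster
    lengths; ``include_primers`` adds them back to give gel-band-scale
    product sizes.  Isoforms missing a primer-bearing block are skipped with
    a warning.
    """
    f_iv, r_iv = sorted(footprints)
    lo, hi = (f_iv[0], r_iv[1]) if include_primers else (f_iv[1], r_iv[0])
    out = []
    for iso in isoforms:
        blocks = iso.all_blocks if isinstance(iso, IsoformStructure) else sorted(iso)
        if include_primers:
            have_f = any(b[0] <= f_iv[0] and f_iv[1] <= b[1] for b in blocks)
            have_r = any(b[0] <= r_iv[0] and r_iv[1] <= b[1] for b in blocks)
        else:
            have_f = any(b[0] <= lo < b[1] for b in blocks)
            have_r = any(b[0] < hi <= b[1] for b in blocks)
        if not (have_f and have_r):
            warnings.warn("isoform lacks a primer-bearing block; skipped")
            continue
        out.append(sum(max(0, min(b[1], hi) - max(b[0], lo)) for b in blocks))
    return out
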