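"""circRNA-specific splicing analysis from BSJ-supporting reads.

Covers intron retention (exon-intron circRNAs), discovery of unannotated
exons via flanking AG-GT splice signatures, microexon classification,
alternative exon usage levels, and the reading-frame consequences of
inserting a novel exon into a coding context.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .bsj_caller import BSJCandidate, CircRNA, _merge_intervals
from .formats_io import GeneModel, fetch

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_IR_MIN_READS = 20
DEFAULT_IR_MIN_COVERAGE = 0.90
DEFAULT_IR_MIN_INTRONIC_FRACTION = 0.03
DEFAULT_NOVEL_MIN_READS = 2
DEFAULT_INTERNAL_DEL_ALLOW = 10
MICROEXON_MIN = 3
MICROEXON_SPLIT = 15
MICROEXON_MAX = 29
USAGE_MIN_READS = {"nick": 10, "panel": 50}


class ExonCategory(str, Enum):
    KNOWN = "known"
    CRYPTIC_NOVEL = "cryptic_novel"
    UNIQUE_NOVEL = "unique_novel"


class MicroexonClass(str, Enum):
    NONE = "none"
    ME_3_15 = "me_3_15"
    ME_16_29 = "me_16_29"


class FrameClass(str, Enum):
    IN_FRAME_NO_STOP = "in_frame_no_stop"
    IN_FRAME_STOP = "in_frame_stop"
    OUT_FRAME_NO_STOP = "out_frame_no_stop"
    OUT_FRAME_STOP = "out_frame_stop"


@dataclass
class IntronStats:
    circ_id: str
    intron: tuple[int, int]
    n_bsj_reads_spanning: int
    intron_coverage_fraction: float
    intronic_fraction: float
    has_novel_exon_inside: bool = False


@dataclass
class NovelExon:
    interval: tuple[int, int]
    strand: str
    n_supporting_reads: int
    category: ExonCategory
    shares_5prime: bool = False
    shares_3prime: bool = False
    frame_class: FrameClass | None = None
    phase_unknown: bool = False

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def microexon_class(self) -> MicroexonClass:
        return classify_microexon(self.length)


@dataclass
class ExonUsage:
    circ_id: str
    exon: tuple[int, int]
    n_reads_spanning: int
    n_reads_using: int
    suppressed: bool

    @property
    def usage_level(self) -> float:
        return self.n_reads_using / self.n_reads_spanning


# ---------------------------------------------------------------------------
# intron retention
# ---------------------------------------------------------------------------

def intron_coverage(
    circ: CircRNA,
    reads: Sequence[BSJCandidate],
    introns: Sequence[tuple[int, int]],
    novel_exons: Sequence[NovelExon] = (),
) -> list[IntronStats]:
    """Per-intron coverage statistics from the circRNA's BSJ-spanning reads.

    For each annotated intron inside the circRNA span: the number of reads
    whose corrected span covers the intron, the fraction of intron positions
    covered by the union of read blocks, and the circRNA-level intronic
    fraction (mean intron-mapped bp divided by mean gene-mapped bp over the
    supporting reads).  Novel exons falling inside an intron set
    ``has_novel_exon_inside``, which vetoes a retained-intron call.
    """
    if not reads:
        return []
    mean_bp_intron = sum(r.bp_intron for r in reads) / len(reads)
    mean_bp_gene = sum(r.bp_gene for r in reads) / len(reads)
    intronic_fraction = mean_bp_intron / mean_bp_gene if mean_bp_gene else 0.0
    out = []
    for intron in sorted(introns):
        s, e = intron
        if e <= s:
            raise ValueError(f"empty intron {intron}")
        spanning = [r for r in reads if r.circ_start <= s and r.circ_end >= e]
        covered = _merge_intervals(
            (max(bs, s), min(be, e))
            for r in spanning
            for bs, be in r.t_blocks
            if min(be, e) > max(bs, s)
        )
        cov_bp = sum(ce - cs for cs, ce in covered)
        has_novel = any(
            ne.category != ExonCategory.KNOWN
            and ne.interval[0] >= s
            and ne.interval[1] <= e
            for ne in novel_exons
        )
        out.append(
            IntronStats(
                circ_id=circ.circ_id,
                intron=intron,
                n_bsj_reads_spanning=len(spanning),
                intron_coverage_fraction=cov_bp / (e - s),
                intronic_fraction=intronic_fraction,
                has_novel_exon_inside=has_novel,
            )
        )
    return out


def call_retained_introns(
    stats: Iterable[IntronStats],
    min_reads: int = DEFAULT_IR_MIN_READS,
    min_cov: float = DEFAULT_IR_MIN_COVERAGE,
    min_intronic_fraction: float = DEFAULT_IR_MIN_INTRONIC_FRACTION,
) -> list[IntronStats]:
    """Call retained introns: >=20 spanning reads, >=90% of the intron length
    covered, circRNA-level intronic fraction above 3%, and no novel exon
    detected inside the intron."""
    return [
        st
        for st in stats
        if st.n_bsj_reads_spanning >= min_reads
        and st.intron_coverage_fraction >= min_cov
        and st.intronic_fraction > min_intronic_fraction
        and not st.has_novel_exon_inside
    ]


# ---------------------------------------------------------------------------
# novel exons
# ---------------------------------------------------------------------------

def _read_segments(
    read: BSJCandidate, internal_del_allow: int
) -> list[tuple[int, int]]:
    """Merge a read's genomic blocks across gaps of <= internal_del_allow bp.

    Small internal deletions are sequencing artifacts, not introns; the
    merged segments are the read's putative exons.  Blocks from the two
    sides of the BSJ are merged per hit so the junction itself never fuses.
    """
    segments = []
    for hit in (read.upstream_hit, read.downstream_hit):
        blocks = sorted(hit.t_blocks)
        if not blocks:
            continue
        cur_s, cur_e = blocks[0]
        for s, e in blocks[1:]:
            if s - cur_e <= internal_del_allow:
                cur_e = max(cur_e, e)
            else:
                segments.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        segments.append((cur_s, cur_e))
    return sorted(segments)


def _has_splice_flanks(genome, chrom: str, start: int, end: int, strand: str) -> bool:
    """Check the AG-exon-GT splice signature in transcript orientation.

    '+' exons need genomic AG at [start-2, start) and GT at [end, end+2);
    '-' exons see the reverse complement, i.e. genomic AC just upstream and
    CT just downstream.
    """
    left = fetch(genome, chrom, start - 2, start)
    right = fetch(genome, chrom, end, end + 2)
    if len(left) != 2 or len(right) != 2:
        return False
    if strand == "+":
        return left == "AG" and right == "GT"
    return left == "AC" and right == "CT"


def similarity(exon_a: tuple[int, int], exon_b: tuple[int, int]) -> float:
    """Jaccard similarity of two exon intervals on one chromosome."""
    inter = max(0, min(exon_a[1], exon_b[1]) - max(exon_a[0], exon_b[0]))
    union = max(exon_a[1], exon_b[1]) - min(exon_a[0], exon_b[0])
    return inter / union if union else 0.0


def _categorize(
    segment: tuple[int, int],
    annotated: Sequence[tuple[int, int]],
    known_similarity: float = 0.95,
) -> tuple[ExonCategory, bool, bool]:
    best = max((similarity(segment, ex) for ex in annotated), default=0.0)
    if best >= known_similarity:
        return ExonCategory.KNOWN, True, True
    overlapping = [
        ex
        for ex in annotated
        if min(segment[1], ex[1]) > max(segment[0], ex[0])
    ]
    if not overlapping:
        return ExonCategory.UNIQUE_NOVEL, False, False
    shares_start = any(ex[0] == segment[0] for ex in overlapping)
    shares_end = any(ex[1] == segment[1] for ex in overlapping)
    return ExonCategory.CRYPTIC_NOVEL, shares_start, shares_end


def detect_novel_exons(
    reads: Sequence[BSJCandidate],
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    min_reads: int = DEFAULT_NOVEL_MIN_READS,
    internal_del_allow: int = DEFAULT_INTERNAL_DEL_ALLOW,
    known_similarity: float = 0.95,
) -> list[NovelExon]:
    """Scan one circRNA's BSJ reads for AG-GT-flanked exon candidates.

    Read blocks separated by at most ``internal_del_allow`` bp merge into
    segments; a segment is an exon candidate iff flanked by the canonical
    splice dinucleotides in transcript orientation.  Identical (start, end)
    segments corroborated by at least ``min_reads`` reads are reported, then
    categorised against annotated exons: Jaccard >= ``known_similarity`` is
    a known exon, partial overlap is a cryptic novel exon (flags record
    which splice site is shared), no overlap is a unique novel exon.  Reads
    whose mapping collapses to a single segment are single-exon evidence and
    do not contribute.  Raw (uncorrected) block coordinates are used: end
    correction would move the very boundaries being tested for flanks.
    """
    if not reads:
        return []
    chrom = reads[0].t_chrom
    strand = reads[0].strand
    annotated = [
        ex
        for m in models
        if m.t_chrom == chrom and m.strand == strand
        for ex in m.exons
    ]
    support: dict[tuple[int, int], int] = {}
    for read in reads:
        segments = _read_segments(read, internal_del_allow)
        if len(segments) < 2:
            continue
        for seg in set(segments):
            support[seg] = support.get(seg, 0) + 1
    out = []
    for seg, n in sorted(support.items()):
        if n < min_reads:
            continue
        if not _has_splice_flanks(genome, chrom, seg[0], seg[1], strand):
            continue
        category, sh5, sh3 = _categorize(seg, annotated, known_similarity)
        if strand == "-":
            # genomic start boundary is the transcript 3' splice site on '-'
            sh5, sh3 = sh3, sh5
        out.append(
            NovelExon(
                interval=seg,
                strand=strand,
                n_supporting_reads=n,
                category=category,
                shares_5prime=sh5,
                shares_3prime=sh3,
            )
        )
    return out


def classify_microexon(length: int) -> MicroexonClass:
    """Microexons are 3-29 nt, split into 3-15 nt and 16-29 nt classes."""
    if length < 1:
        raise ValueError("exon length must be positive")
    if MICROEXON_MIN <= length <= MICROEXON_SPLIT:
        return MicroexonClass.ME_3_15
    if MICROEXON_SPLIT < length <= MICROEXON_MAX:
        return MicroexonClass.ME_16_29
    return MicroexonClass.NONE


# ---------------------------------------------------------------------------
# reading frame
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _has_stop_in_phase(seq: str, phase: int) -> bool:
    # phase = bases of the upstream codon completed inside this exon
    offset = (3 - phase) % 3
    return any(
        seq[i : i + 3] in STOP_CODONS for i in range(offset, len(seq) - 2, 3)
    )


def exon_frame_analysis(
    exon_interval: tuple[int, int],
    strand: str,
    upstream_exon_phase: int | None,
    genome: Mapping[str, str],
    chrom: str,
) -> tuple[FrameClass, bool]:
    """Classify the coding consequence of inserting an exon.

    The exon is in-frame iff its length is a multiple of 3 (no frameshift of
    downstream exons).  Stop codons are scanned in the single reading frame
    dictated by the upstream exon's phase, over codons fully inside the
    exon.  With no coding upstream exon (phase None) all three phases are
    scanned and the result is flagged phase-unknown (a stop in any phase
    counts).  Returns (frame_class, phase_unknown).
    """
    start, end = exon_interval
    seq = fetch(genome, chrom, start, end)
    if strand == "-":
        seq = _revcomp(seq)
    in_frame = (end - start) % 3 == 0
    if upstream_exon_phase is None:
        stop = any(_has_stop_in_phase(seq, p) for p in (0, 1, 2))
        unknown = True
    else:
        if upstream_exon_phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {upstream_exon_phase}")
        stop = _has_stop_in_phase(seq, upstream_exon_phase)
        unknown = False
    if in_frame:
        cls = FrameClass.IN_FRAME_STOP if stop else FrameClass.IN_FRAME_NO_STOP
    else:
        cls = FrameClass.OUT_FRAME_STOP if stop else FrameClass.OUT_FRAME_NO_STOP
    return cls, unknown


def upstream_phase(
    exon_interval: tuple[int, int], model: GeneModel
) -> int | None:
    """Phase entering a (novel) exon, dictated by the nearest annotated exon
    upstream in transcript orientation; None when no phased exon precedes."""
    if model.coding_phases is None:
        return None
    if model.strand == "+":
        candidates = [
            (e, p)
            for (s, e), p in zip(model.exons, model.coding_phases)
            if e <= exon_interval[0]
        ]
        if not candidates:
            return None
        (s_e, phase) = max(candidates)
        up = next((s, e) for (s, e) in model.exons if e == s_e)
    else:
        candidates = [
            (s, p)
            for (s, e), p in zip(model.exons, model.coding_phases)
            if s >= exon_interval[1]
        ]
        if not candidates:
            return None
        (s_s, phase) = min(candidates)
        up = next((s, e) for (s, e) in model.exons if s == s_s)
    return (phase + (up[1] - up[0])) % 3


# ---------------------------------------------------------------------------
# exon usage
# ---------------------------------------------------------------------------

def exon_usage(
    circ: CircRNA,
    reads: Sequence[BSJCandidate],
    exon: tuple[int, int],
    mode: str = "nick",
    min_reads: int | None = None,
    min_use_bp: int = 1,
) -> ExonUsage | None:
    """Exon usage level: reads using the exon over reads spanning it.

    A read spans the exon when its corrected genomic span contains the exon
    interval entirely (a partial span cannot witness exclusion); it uses the
    exon when at least ``min_use_bp`` of its mapped blocks fall inside.
    Constitutive exons score 1, unused exons 0.  Records with fewer using
    reads than the mode's gate (10 for global nicked-circRNA runs, 50 for
    targeted panel runs) are marked suppressed.  Returns None when no read
    spans the exon (level undefined).
    """
    if min_reads is None:
        min_reads = USAGE_MIN_READS[mode]
    s, e = exon
    spanning = [r for r in reads if r.circ_start <= s and r.circ_end >= e]
    if not spanning:
        return None
    using = [
        r
        for r in spanning
        if sum(
            max(0, min(be, e) - max(bs, s)) for bs, be in r.t_blocks
        )
        >= min_use_bp
    ]
    return ExonUsage(
        circ_id=circ.circ_id,
        exon=exon,
        n_reads_spanning=len(spanning),
        n_reads_using=len(using),
        suppressed=len(using) < min_reads,
    )


def linear_inclusion(
    read_spans: Sequence[tuple[int, int]],
    read_blocks: Sequence[Sequence[tuple[int, int]]],
    exon: tuple[int, int],
    flanking: tuple[tuple[int, int], tuple[int, int]],
) -> float | None:
    """Fraction of linear-transcript reads including an exon with both
    neighbours; the circRNA-vs-linear comparison statistic.

    Considers reads whose span covers both flanking exons; a read includes
    the exon when any of its blocks overlaps it.  None when no read spans.
    """
    lo = min(flanking[0][0], flanking[1][0])
    hi = max(flanking[0][1], flanking[1][1])
    spanning_idx = [
        i for i, (s, e) in enumerate(read_spans) if s <= lo and e >= hi
    ]
    if not spanning_idx:
        return None
    including = sum(
        1
        for i in spanning_idx
        if any(
            min(be, exon[1]) > max(bs, exon[0]) for bs, be in read_blocks[i]
        )
    )
    return including / len(spanning_idx)
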