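"""Back-splice-junction calling from per-read split alignments.

A read crossing a back-splice junction aligns as two genomic segments in
reversed order on the read: the read-5' segment lands on the genomically
downstream part of the locus.  This module pairs per-read hits into BSJ
candidates, scores and filters them, corrects heterogeneous read ends
against exon annotation or known-circRNA catalogs, and collapses the
accepted candidates into a unique-circRNA table.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import AlignmentHit, GeneModel, KnownCircRecord

MITO_CHROMS = frozenset({"chrM", "chrMT", "MT", "M"})

DEFAULT_MIN_SCORE = 30
DEFAULT_MAX_SPAN = 1_000_000
DEFAULT_OVERLAP_REJECT = 50
DEFAULT_SNAP_BP = 30
DEFAULT_KNOWN_JACCARD = 0.95


class ReadClassLabel(str, Enum):
    BSJ_TWO_HIT = "bsj_two_hit"
    MULTI_ROUND = "multi_round"
    LINEAR_LIKE = "linear_like"
    UNMAPPED_FOR_CIRC = "unmapped_for_circ"


@dataclass
class ReadClass:
    read_id: str
    label: ReadClassLabel
    candidate: "BSJCandidate | None" = None


@dataclass
class Rejection:
    """A failed pairing or end-correction, tagged with the first failed rule."""

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass
class BSJCandidate:
    """An accepted two-hit pairing defining a putative circRNA span."""

    read_id: str
    t_chrom: str
    strand: str
    circ_start: int
    circ_end: int
    upstream_hit: AlignmentHit    # genomically left (lower coordinates)
    downstream_hit: AlignmentHit  # genomically right
    score_left: int
    score_right: int
    bp_gene: int = 0
    bp_exon: int = 0
    bp_intron: int = 0
    bp_est: int = 0
    adjust_left: int = 0
    adjust_right: int = 0
    db_ids: dict[str, str] = field(default_factory=dict)
    corrected: bool = False

    @property
    def total_adjustment(self) -> int:
        """Total bp of end correction applied to this read (sum of both ends)."""
        return abs(self.adjust_left) + abs(self.adjust_right)

    @property
    def t_blocks(self) -> list[tuple[int, int]]:
        """Merged genomic block intervals from both hits, sorted."""
        return sorted(self.upstream_hit.t_blocks + self.downstream_hit.t_blocks)


@dataclass
class CircRNA:
    """A collapsed unique circRNA region with read support and metadata."""

    t_chrom: str
    strand: str
    start: int
    end: int
    n_reads: int
    host_gene: str | None
    db_ids: dict[str, str]
    mean_bp_gene: float
    mean_bp_exon: float
    mean_bp_intron: float
    mean_bp_est: float
    adjust_min: int
    adjust_max: int
    adjust_mean: float
    is_novel: bool
    supporting: list[BSJCandidate] = field(default_factory=list)

    @property
    def circ_id(self) -> str:
        return f"{self.t_chrom}:{self.start}-{self.end}({self.strand})"


# ---------------------------------------------------------------------------
# scoring and pairing
# ---------------------------------------------------------------------------

def blat_score(hit: AlignmentHit) -> int:
    """BLAT-style alignment score: matches minus mismatches and gap openings."""
    return hit.matches - hit.mismatches - hit.q_gap_count - hit.t_gap_count


def pair_hits(
    hit_a: AlignmentHit,
    hit_b: AlignmentHit,
    min_score: int = DEFAULT_MIN_SCORE,
    max_span: int = DEFAULT_MAX_SPAN,
    overlap_reject: int = DEFAULT_OVERLAP_REJECT,
) -> BSJCandidate | Rejection:
    """Pair two hits from one read into a BSJ candidate or a tagged rejection.

    ``hit_a`` must precede ``hit_b`` on the read axis.  Acceptance requires:
    same chromosome and strand; combined genomic span <= ``max_span``;
    genomic overlap of the two hits < ``overlap_reject`` bp; back-splice
    geometry (the read-earlier hit maps genomically downstream in transcript
    orientation: greater coordinates on '+', smaller on '-'); and a score of
    at least ``min_score`` on each side of the junction.  The returned
    Rejection names the first criterion that failed.
    """
    if hit_a.read_id != hit_b.read_id:
        raise ValueError("pair_hits requires two hits from the same read")
    if hit_a.q_start >= hit_b.q_start:
        hit_a, hit_b = hit_b, hit_a
    if hit_a.t_chrom != hit_b.t_chrom:
        return Rejection("chromosome")
    if hit_a.strand != hit_b.strand:
        return Rejection("strand")
    start = min(hit_a.t_start, hit_b.t_start)
    end = max(hit_a.t_end, hit_b.t_end)
    if end - start > max_span:
        return Rejection("distance")
    overlap = min(hit_a.t_end, hit_b.t_end) - max(hit_a.t_start, hit_b.t_start)
    if overlap >= overlap_reject:
        return Rejection("overlap")
    if hit_a.strand == "+":
        reversed_order = hit_a.t_start > hit_b.t_start
    else:
        reversed_order = hit_a.t_start < hit_b.t_start
    if not reversed_order:
        return Rejection("order")
    score_a, score_b = blat_score(hit_a), blat_score(hit_b)
    if score_a < min_score or score_b < min_score:
        return Rejection("score")
    upstream, downstream = (
        (hit_a, hit_b) if hit_a.t_start <= hit_b.t_start else (hit_b, hit_a)
    )
    return BSJCandidate(
        read_id=hit_a.read_id,
        t_chrom=hit_a.t_chrom,
        strand=hit_a.strand,
        circ_start=start,
        circ_end=end,
        upstream_hit=upstream,
        downstream_hit=downstream,
        score_left=blat_score(upstream),
        score_right=blat_score(downstream),
    )


def classify_read_hits(
    hits: Sequence[AlignmentHit],
    min_score: int = DEFAULT_MIN_SCORE,
    max_span: int = DEFAULT_MAX_SPAN,
    overlap_reject: int = DEFAULT_OVERLAP_REJECT,
) -> ReadClass:
    """Assign one read's hits to a mutually exclusive evidence class.

    Exactly two hits that pass all pairing rules give ``bsj_two_hit`` (with
    the candidate attached).  Three or more hits tiling one (chrom, strand)
    locus with at least two junction-crossing adjacencies on the read axis
    are a rolling-RT concatemer, ``multi_round``; these support the locus
    but are counted separately so concatemers cannot inflate quantification.
    Reads whose hits never reach the score threshold are
    ``unmapped_for_circ``; everything else is ``linear_like``.
    """
    if not hits:
        raise ValueError("classify_read_hits requires at least one hit")
    read_id = hits[0].read_id
    if any(h.read_id != read_id for h in hits):
        raise ValueError("all hits must come from one read")
    ordered = sorted(hits, key=lambda h: h.q_start)
    if len(ordered) == 2:
        cand = pair_hits(
            ordered[0], ordered[1],
            min_score=min_score, max_span=max_span, overlap_reject=overlap_reject,
        )
        if isinstance(cand, BSJCandidate):
            return ReadClass(read_id, ReadClassLabel.BSJ_TWO_HIT, cand)
    elif len(ordered) >= 3:
        same_locus = (
            len({h.t_chrom for h in ordered}) == 1
            and len({h.strand for h in ordered}) == 1
            and max(h.t_end for h in ordered) - min(h.t_start for h in ordered)
            <= max_span
        )
        if same_locus and all(blat_score(h) >= min_score for h in ordered):
            strand = ordered[0].strand
            # a junction-crossing adjacency breaks colinearity: the next read
            # segment starts genomically before the current one ends (on '-',
            # after it starts), i.e. the alignment wrapped around the circle
            wraps = 0
            for cur, nxt in zip(ordered, ordered[1:]):
                if (strand == "+" and nxt.t_start < cur.t_end) or (
                    strand == "-" and nxt.t_end > cur.t_start
                ):
                    wraps += 1
            if wraps >= 2:
                return ReadClass(read_id, ReadClassLabel.MULTI_ROUND)
    if all(blat_score(h) < min_score for h in ordered):
        return ReadClass(read_id, ReadClassLabel.UNMAPPED_FOR_CIRC)
    return ReadClass(read_id, ReadClassLabel.LINEAR_LIKE)


# ---------------------------------------------------------------------------
# annotation overlap
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def _overlap_bp(blocks: Iterable[tuple[int, int]], merged: list[tuple[int, int]]) -> int:
    if not merged:
        return 0
    starts = [s for s, _ in merged]
    total = 0
    for bs, be in blocks:
        i = max(bisect_right(starts, bs) - 1, 0)
        while i < len(merged) and merged[i][0] < be:
            s, e = merged[i]
            total += max(0, min(be, e) - max(bs, s))
            i += 1
    return total


class AnnotationIndex:
    """Per-chromosome merged gene/exon/intron/EST layers for overlap queries."""

    def __init__(
        self,
        models: Sequence[GeneModel],
        ests: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    ):
        self.models = list(models)
        self._layers: dict[str, dict[str, list[tuple[int, int]]]] = {}
        per_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for m in models:
            layers = per_chrom.setdefault(
                m.t_chrom, {"gene": [], "exon": [], "intron": [], "est": []}
            )
            layers["gene"].append((m.start, m.end))
            layers["exon"].extend(m.exons)
            layers["intron"].extend(m.introns)
        if ests:
            for chrom, ivs in ests.items():
                per_chrom.setdefault(
                    chrom, {"gene": [], "exon": [], "intron": [], "est": []}
                )["est"].extend(ivs)
        for chrom, layers in per_chrom.items():
            self._layers[chrom] = {k: _merge_intervals(v) for k, v in layers.items()}

    def overlaps(self, chrom: str, blocks: Iterable[tuple[int, int]]):
        layers = self._layers.get(chrom)
        if layers is None:
            return 0, 0, 0, 0
        blocks = list(blocks)
        return tuple(
            _overlap_bp(blocks, layers[k]) for k in ("gene", "exon", "intron", "est")
        )


def annotate_hit(
    hit: AlignmentHit,
    index: AnnotationIndex,
) -> tuple[int, int, int, int]:
    """Summed bp overlap of a hit's blocks with gene/exon/intron/EST layers.

    Layers are independent: exon + intron need not equal gene where models
    disagree.  An unannotated chromosome yields all zeros.
    """
    return index.overlaps(hit.t_chrom, hit.t_blocks)


def annotate_candidate(cand: BSJCandidate, index: AnnotationIndex) -> BSJCandidate:
    """Sum per-hit annotation overlaps into the combined candidate."""
    g1 = annotate_hit(cand.upstream_hit, index)
    g2 = annotate_hit(cand.downstream_hit, index)
    cand.bp_gene, cand.bp_exon, cand.bp_intron, cand.bp_est = (
        a + b for a, b in zip(g1, g2)
    )
    return cand


# ---------------------------------------------------------------------------
# end correction
# ---------------------------------------------------------------------------

def span_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard similarity of two genomic spans on one chromosome."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


def _nearest_boundary(
    pos: int, boundaries: Sequence[int], snap_bp: int, prefer_low: bool
) -> int | None:
    """Nearest boundary within snap_bp; ties prefer the boundary extending the
    circRNA (lower for the start side, higher for the end side), then the
    smaller coordinate."""
    best: int | None = None
    best_key: tuple | None = None
    for b in boundaries:
        d = abs(b - pos)
        if d > snap_bp:
            continue
        # tie-break: distance, then longer circ (lower b for start / higher for end)
        key = (d, b if prefer_low else -b, b)
        if best_key is None or key < best_key:
            best, best_key = b, key
    return best


def correct_ends(
    cand: BSJCandidate,
    models: Sequence[GeneModel],
    known: Sequence[KnownCircRecord],
    snap_bp: int = DEFAULT_SNAP_BP,
    min_known_overlap: float = DEFAULT_KNOWN_JACCARD,
) -> BSJCandidate | Rejection:
    """Snap heterogeneous circRNA ends to annotation, or reject the read.

    Nanopore read ends are ragged, so a candidate is accepted only if its
    ends can be anchored: (1) if both ends lie within ``snap_bp`` of an
    annotated exon boundary on the candidate strand (acceptor side for the
    start, donor side for the end, in genomic coordinates: exon starts for
    circ_start, exon ends for circ_end), each end snaps to its nearest such
    boundary; (2) otherwise, if the span's Jaccard overlap with a known
    circRNA record reaches ``min_known_overlap``, the ends snap to that
    record and its database ids attach; (3) otherwise the read is rejected
    and excluded from circRNA calling.
    """
    starts: list[int] = []
    ends: list[int] = []
    for m in models:
        if m.t_chrom != cand.t_chrom or m.strand != cand.strand or m.is_rRNA:
            continue
        for s, e in m.exons:
            starts.append(s)
            ends.append(e)
    new_start = _nearest_boundary(cand.circ_start, starts, snap_bp, prefer_low=True)
    new_end = _nearest_boundary(cand.circ_end, ends, snap_bp, prefer_low=False)
    if new_start is not None and new_end is not None and new_start < new_end:
        cand.adjust_left = new_start - cand.circ_start
        cand.adjust_right = new_end - cand.circ_end
        cand.circ_start, cand.circ_end = new_start, new_end
        cand.corrected = True
        return cand

    best: KnownCircRecord | None = None
    best_j = 0.0
    for rec in known:
        if rec.t_chrom != cand.t_chrom or rec.strand != cand.strand:
            continue
        j = span_jaccard((cand.circ_start, cand.circ_end), (rec.start, rec.end))
        if j > best_j:
            best, best_j = rec, j
    if best is not None and best_j >= min_known_overlap:
        cand.adjust_left = best.start - cand.circ_start
        cand.adjust_right = best.end - cand.circ_end
        cand.circ_start, cand.circ_end = best.start, best.end
        cand.db_ids[best.db_name] = best.circ_id
        cand.corrected = True
        return cand
    return Rejection("uncorrectable_ends")


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

def _attach_db_ids(
    chrom: str, strand: str, start: int, end: int, known: Sequence[KnownCircRecord]
) -> dict[str, str]:
    return {
        rec.db_name: rec.circ_id
        for rec in known
        if rec.t_chrom == chrom
        and rec.strand == strand
        and rec.start == start
        and rec.end == end
    }


def collapse_circRNAs(
    cands: Sequence[BSJCandidate],
    models: Sequence[GeneModel],
    known: Sequence[KnownCircRecord] = (),
) -> list[CircRNA]:
    """Collapse end-corrected candidates into one row per unique circRNA.

    Candidates on mitochondrial chromosomes or overlapping rRNA gene models
    are removed before collapsing.  Per circRNA the read count, mean
    annotation overlaps, end-adjustment statistics, exact-coordinate
    database ids and the host gene (maximal span overlap) are recorded.
    """
    rrna = [
        (m.t_chrom, m.start, m.end) for m in models if m.is_rRNA
    ]

    def excluded(c: BSJCandidate) -> bool:
        if c.t_chrom in MITO_CHROMS:
            return True
        for chrom, s, e in rrna:
            if chrom == c.t_chrom and min(c.circ_end, e) > max(c.circ_start, s):
                return True
        return False

    groups: dict[tuple[str, str, int, int], list[BSJCandidate]] = {}
    for c in cands:
        if not c.corrected:
            raise ValueError(f"candidate for read {c.read_id} is not end-corrected")
        if excluded(c):
            continue
        groups.setdefault((c.t_chrom, c.strand, c.circ_start, c.circ_end), []).append(c)

    out: list[CircRNA] = []
    for (chrom, strand, start, end), members in sorted(groups.items()):
        adjustments = [m.total_adjustment for m in members]
        db_ids: dict[str, str] = {}
        for m in members:
            db_ids.update(m.db_ids)
        db_ids.update(_attach_db_ids(chrom, strand, start, end, known))
        host, host_ov = None, 0
        for gm in models:
            if gm.t_chrom != chrom or gm.is_rRNA:
                continue
            ov = min(end, gm.end) - max(start, gm.start)
            if ov > host_ov:
                host, host_ov = gm.gene_id, ov
        n = len(members)
        out.append(
            CircRNA(
                t_chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                n_reads=n,
                host_gene=host,
                db_ids=db_ids,
                mean_bp_gene=sum(m.bp_gene for m in members) / n,
                mean_bp_exon=sum(m.bp_exon for m in members) / n,
                mean_bp_intron=sum(m.bp_intron for m in members) / n,
                mean_bp_est=sum(m.bp_est for m in members) / n,
                adjust_min=min(adjustments),
                adjust_max=max(adjustments),
                adjust_mean=sum(adjustments) / n,
                is_novel=not db_ids,
                supporting=list(members),
            )
        )
    return out


def circ_table(circs: Sequence[CircRNA]) -> pd.DataFrame:
    """Flatten CircRNA records into the tab-separated output table."""
    rows = []
    for c in circs:
        rows.append(
            {
                "chrom": c.t_chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "n_reads": c.n_reads,
                "host_gene": c.host_gene or ".",
                "circbase_id": c.db_ids.get("circbase", "."),
                "circatlas_id": c.db_ids.get("circatlas", "."),
                "circpedia_id": c.db_ids.get("circpedia", "."),
                "mean_bp_gene": c.mean_bp_gene,
                "mean_bp_exon": c.mean_bp_exon,
                "mean_bp_intron": c.mean_bp_intron,
                "mean_bp_est": c.mean_bp_est,
                "adjust_min": c.adjust_min,
                "adjust_max": c.adjust_max,
                "adjust_mean": c.adjust_mean,
                "is_novel": c.is_novel,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "n_reads", "host_gene",
            "circbase_id", "circatlas_id", "circpedia_id",
            "mean_bp_gene", "mean_bp_exon", "mean_bp_intron", "mean_bp_est",
            "adjust_min", "adjust_max", "adjust_mean", "is_novel",
        ],
    )


# ---------------------------------------------------------------------------
# run summary
# ---------------------------------------------------------------------------

def summarize_run(
    read_classes: Sequence[ReadClass],
    circs: Sequence[CircRNA],
    filtered_reads: int,
) -> dict:
    """Table-1-style run accounting with fractions of filtered reads.

    Fractions are percentages of ``filtered_reads`` rounded to two decimals;
    with zero filtered reads they are reported as None and flagged.
    """
    n_bsj = sum(1 for rc in read_classes if rc.label == ReadClassLabel.BSJ_TWO_HIT)
    n_multi = sum(1 for rc in read_classes if rc.label == ReadClassLabel.MULTI_ROUND)
    circ_mapping = sum(c.n_reads for c in circs)
    per_db: dict[str, int] = {}
    for c in circs:
        for db in c.db_ids:
            per_db[db] = per_db.get(db, 0) + 1

    def pct(count: int) -> float | None:
        if filtered_reads <= 0:
            return None
        return round(100.0 * count / filtered_reads, 2)

    return {
        "filtered_reads": filtered_reads,
        "bsj_reads": n_bsj,
        "bsj_reads_pct": pct(n_bsj),
        "circ_mapping_reads": circ_mapping,
        "circ_mapping_reads_pct": pct(circ_mapping),
        "unique_circRNAs": len(circs),
        "per_database": per_db,
        "novel_circRNAs": sum(1 for c in circs if c.is_novel),
        "multi_round_reads": n_multi,
        "fractions_defined": filtered_reads > 0,
    }
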