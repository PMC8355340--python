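"""Cross-assembly circRNA conservation via 20-bp end-anchor liftover.

A circRNA's BSJ is defined by its two genomic ends.  To compare catalogs
between assemblies (e.g. human hg19 and mouse mm10), 20 bp from each end of
every circRNA are lifted through a chain map, recombined into a BSJ, and
compared to the other catalog; a pair is conserved only when the match is
exact in both directions.  Internal splice structure is deliberately
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .bsj_caller import CircRNA
from .formats_io import Chain, ChainMap

ANCHOR_LEN = 20


@dataclass
class LiftResult:
    circ_id: str
    lifted_start_anchor: tuple[str, int, int] | None
    lifted_end_anchor: tuple[str, int, int] | None
    recombined_bsj: tuple[str, int, int, str] | None
    matched_circ_id: str | None = None
    reciprocal_ok: bool = False


def _lift_through(chain: Chain, chrom: str, start: int, end: int):
    """Map [start, end) through one chain; None unless every base sits in a
    single ungapped block (a base in a chain gap is unmappable)."""
    for t0, q0, size in chain.aligned_blocks():
        if start >= t0 and end <= t0 + size:
            qs = q0 + (start - t0)
            qe = q0 + (end - t0)
            if chain.q_strand == "-":
                qs, qe = chain.q_size - qe, chain.q_size - qs
            return chain.q_name, qs, qe, chain.q_strand
        if t0 >= end:
            break
    return None


def lift_anchor(
    interval: tuple[str, int, int], chains: ChainMap
) -> tuple[str, int, int, str] | None:
    """Lift one anchor interval through the best covering chain.

    Chains covering all bases compete by score (ties broken by file order);
    returns (chrom, start, end, chain_strand) in forward target coordinates,
    or None when unmapped.
    """
    chrom, start, end = interval
    best = None
    best_score = None
    for chain in chains.for_chrom(chrom):
        if start < chain.t_start or end > chain.t_end:
            continue
        lifted = _lift_through(chain, chrom, start, end)
        if lifted is not None and (best_score is None or chain.score > best_score):
            best, best_score = lifted, chain.score
    return best


def _lift_bsj(
    circ: CircRNA, chains: ChainMap, anchor_len: int = ANCHOR_LEN
) -> LiftResult:
    start_anchor = (circ.t_chrom, circ.start, circ.start + anchor_len)
    end_anchor = (circ.t_chrom, circ.end - anchor_len, circ.end)
    la = lift_anchor(start_anchor, chains)
    lb = lift_anchor(end_anchor, chains)
    result = LiftResult(
        circ_id=circ.circ_id,
        lifted_start_anchor=la[:3] if la else None,
        lifted_end_anchor=lb[:3] if lb else None,
        recombined_bsj=None,
    )
    if la is None or lb is None:
        return result
    if la[0] != lb[0] or la[3] != lb[3]:
        return result
    flip = la[3] == "-"
    strand = circ.strand
    if flip:
        strand = "-" if strand == "+" else "+"
    start = min(la[1], lb[1])
    end = max(la[2], lb[2])
    if end - start < 2 * anchor_len:
        return result  # anchors collapsed or crossed; not a valid BSJ
    result.recombined_bsj = (la[0], start, end, strand)
    return result


def conserved_circRNAs(
    set_a: Sequence[CircRNA],
    set_b: Sequence[CircRNA],
    chains_ab: ChainMap,
    chains_ba: ChainMap,
    anchor_len: int = ANCHOR_LEN,
) -> tuple[list[tuple[CircRNA, CircRNA]], float, float, list[LiftResult]]:
    """Reciprocal exact-match conservation between two circRNA catalogs.

    A pair (a, b) is conserved iff lifting a's end anchors A->B recombines
    to exactly b's BSJ coordinates AND lifting b's anchors B->A recombines
    to exactly a's.  Returns (pairs, pct_of_set_a, pct_of_set_b, lift
    results for set A); percentages count distinct conserved circRNAs per
    set on the 0-100 scale.
    """
    index_b = {(c.t_chrom, c.start, c.end, c.strand): c for c in set_b}
    index_a = {(c.t_chrom, c.start, c.end, c.strand): c for c in set_a}
    pairs: list[tuple[CircRNA, CircRNA]] = []
    lifts_a: list[LiftResult] = []
    for a in set_a:
        res = _lift_bsj(a, chains_ab, anchor_len)
        lifts_a.append(res)
        if res.recombined_bsj is None:
            continue
        b = index_b.get(res.recombined_bsj)
        if b is None:
            continue
        back = _lift_bsj(b, chains_ba, anchor_len)
        if back.recombined_bsj is None:
            continue
        if index_a.get(back.recombined_bsj) is a:
            res.matched_circ_id = b.circ_id
            res.reciprocal_ok = True
            pairs.append((a, b))
    conserved_a = {id(a) for a, _ in pairs}
    conserved_b = {id(b) for _, b in pairs}
    pct_a = 100.0 * len(conserved_a) / len(set_a) if set_a else 0.0
    pct_b = 100.0 * len(conserved_b) / len(set_b) if set_b else 0.0
    return pairs, pct_a, pct_b, lifts_a
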