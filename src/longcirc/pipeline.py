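"""End-to-end orchestration: filter -> call -> splicing features -> conserve.

A run is fully determined by its PipelineConfig plus the input files; every
stage writes plain-text tables and the run summary mirrors the read-class
accounting of a sequencing experiment (filtered reads, BSJ reads and their
percentage, circRNA-mapping reads, unique circRNAs, per-database known
counts, novel circRNAs, multi-round concatemer reads).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import bsj_caller as bc
from . import conservation as cons
from . import splice_features as sf
from .formats_io import (
    parse_psl,
    read_chain,
    read_fasta,
    read_fastq,
    read_gene_models,
    read_known_circs,
    filter_reads,
    write_bed12,
)

logger = logging.getLogger("longcirc")


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, defaulting to the published values."""

    mode: str = "nick"  # 'nick' (global) or 'panel' (targeted, deeper)
    min_qual: float = 7.0
    min_len: int = 250
    min_score: int = bc.DEFAULT_MIN_SCORE
    max_span: int = bc.DEFAULT_MAX_SPAN
    overlap_reject: int = bc.DEFAULT_OVERLAP_REJECT
    snap_bp: int = bc.DEFAULT_SNAP_BP
    known_jaccard: float = bc.DEFAULT_KNOWN_JACCARD
    ir_min_reads: int = sf.DEFAULT_IR_MIN_READS
    ir_min_cov: float = sf.DEFAULT_IR_MIN_COVERAGE
    ir_min_intronic_fraction: float = sf.DEFAULT_IR_MIN_INTRONIC_FRACTION
    novel_min_reads: int = sf.DEFAULT_NOVEL_MIN_READS
    internal_del_allow: int = sf.DEFAULT_INTERNAL_DEL_ALLOW
    polyA_k: int = 7
    seed: int = 0

    @property
    def usage_min_reads(self) -> int:
        return sf.USAGE_MIN_READS[self.mode]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class CallResult:
    read_classes: list[bc.ReadClass]
    circs: list[bc.CircRNA]
    filtered_reads: int
    summary: dict = field(default_factory=dict)


def call_circRNAs(
    hits,
    models,
    known,
    config: PipelineConfig,
    filtered_read_ids: set[str] | None = None,
) -> CallResult:
    """Classify per-read hits, correct ends, collapse, and summarise.

    ``filtered_read_ids`` restricts calling to reads that survived quality
    filtering (None means all hits are eligible, e.g. when the FASTQ is not
    available)."""
    per_read: dict[str, list] = {}
    for hit in hits:
        if filtered_read_ids is not None and hit.read_id not in filtered_read_ids:
            continue
        per_read.setdefault(hit.read_id, []).append(hit)
    index = bc.AnnotationIndex(models)
    read_classes: list[bc.ReadClass] = []
    corrected: list[bc.BSJCandidate] = []
    for read_id in sorted(per_read):
        rc = bc.classify_read_hits(
            per_read[read_id],
            min_score=config.min_score,
            max_span=config.max_span,
            overlap_reject=config.overlap_reject,
        )
        read_classes.append(rc)
        if rc.label is not bc.ReadClassLabel.BSJ_TWO_HIT:
            continue
        cand = bc.annotate_candidate(rc.candidate, index)
        fixed = bc.correct_ends(
            cand, models, known,
            snap_bp=config.snap_bp, min_known_overlap=config.known_jaccard,
        )
        if isinstance(fixed, bc.BSJCandidate):
            corrected.append(fixed)
    circs = bc.collapse_circRNAs(corrected, models, known)
    n_filtered = (
        len(filtered_read_ids) if filtered_read_ids is not None else len(per_read)
    )
    summary = bc.summarize_run(read_classes, circs, n_filtered)
    return CallResult(
        read_classes=read_classes,
        circs=circs,
        filtered_reads=n_filtered,
        summary=summary,
    )


def analyse_features(
    circs, genome, models, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Intron-retention, novel-exon and exon-usage tables for called circRNAs."""
    gene_by_id = {m.gene_id: m for m in models}
    intron_rows, exon_rows, usage_rows = [], [], []
    for circ in circs:
        host = gene_by_id.get(circ.host_gene)
        if host is None:
            continue
        novel = sf.detect_novel_exons(
            circ.supporting, genome, models,
            min_reads=config.novel_min_reads,
            internal_del_allow=config.internal_del_allow,
        )
        for ne in novel:
            if ne.category is sf.ExonCategory.KNOWN:
                continue
            phase = sf.upstream_phase(ne.interval, host)
            frame, unknown = sf.exon_frame_analysis(
                ne.interval, ne.strand, phase, genome, circ.t_chrom
            )
            ne.frame_class, ne.phase_unknown = frame, unknown
            exon_rows.append(
                {
                    "circ_id": circ.circ_id,
                    "start": ne.interval[0],
                    "end": ne.interval[1],
                    "strand": ne.strand,
                    "n_reads": ne.n_supporting_reads,
                    "category": ne.category.value,
                    "length": ne.length,
                    "microexon_class": ne.microexon_class.value,
                    "frame_class": frame.value,
                    "phase_unknown": unknown,
                }
            )
        introns = [
            iv
            for iv in host.introns
            if iv[0] >= circ.start and iv[1] <= circ.end
        ]
        stats = sf.intron_coverage(circ, circ.supporting, introns, novel)
        retained = {
            st.intron
            for st in sf.call_retained_introns(
                stats,
                min_reads=config.ir_min_reads,
                min_cov=config.ir_min_cov,
                min_intronic_fraction=config.ir_min_intronic_fraction,
            )
        }
        for st in stats:
            intron_rows.append(
                {
                    "circ_id": st.circ_id,
                    "intron_start": st.intron[0],
                    "intron_end": st.intron[1],
                    "n_spanning_reads": st.n_bsj_reads_spanning,
                    "coverage": st.intron_coverage_fraction,
                    "intronic_fraction": st.intronic_fraction,
                    "has_novel_exon_inside": st.has_novel_exon_inside,
                    "retained": st.intron in retained,
                }
            )
        usage_targets = [
            ex for ex in host.exons if ex[0] >= circ.start and ex[1] <= circ.end
        ] + [ne.interval for ne in novel if ne.category is not sf.ExonCategory.KNOWN]
        for ex in sorted(set(usage_targets)):
            usage = sf.exon_usage(
                circ, circ.supporting, ex, mode=config.mode
            )
            if usage is None:
                continue
            usage_rows.append(
                {
                    "circ_id": circ.circ_id,
                    "exon_start": ex[0],
                    "exon_end": ex[1],
                    "n_spanning": usage.n_reads_spanning,
                    "n_using": usage.n_reads_using,
                    "usage_level": usage.usage_level,
                    "suppressed": usage.suppressed,
                }
            )
    return (
        pd.DataFrame(intron_rows),
        pd.DataFrame(exon_rows),
        pd.DataFrame(usage_rows),
    )


def run_pipeline(
    config: PipelineConfig,
    psl_path,
    genes_path,
    out_dir,
    fastq_path=None,
    genome_path=None,
    known_paths=(),
    chain_ab_path=None,
    chain_ba_path=None,
    circs_b: list | None = None,
    force: bool = False,
) -> dict:
    """Run filter -> call -> features -> conserve and write all outputs.

    Re-running with an identical config hash on an existing output directory
    is a no-op unless ``force``.  Returns the run summary dict.
    """
    out = Path(out_dir)
    stamp = out / "config.json"
    if stamp.exists() and not force:
        previous = json.loads(stamp.read_text())
        if previous.get("digest") == config.digest():
            logger.info("outputs up to date for config %s; skipping", config.digest())
            return json.loads((out / "summary.json").read_text())
    out.mkdir(parents=True, exist_ok=True)

    filtered_ids: set[str] | None = None
    if fastq_path is not None:
        filtered = filter_reads(
            read_fastq(fastq_path), min_quality=config.min_qual,
            min_length=config.min_len,
        )
        filtered_ids = {r.read_id for r in filtered}
        logger.info("filtered reads: %d", len(filtered_ids))

    with open(psl_path) as fh:
        hits = list(parse_psl(fh))
    models = read_gene_models(genes_path)
    known = []
    for path in known_paths:
        known.extend(read_known_circs(path))

    result = call_circRNAs(hits, models, known, config, filtered_ids)
    bc.circ_table(result.circs).to_csv(out / "circRNAs.tsv", sep="\t", index=False)
    write_bed12(
        (
            (
                c.t_chrom, c.start, c.end, c.circ_id, c.n_reads, c.strand,
                bc._merge_intervals(
                    iv
                    for r in c.supporting
                    for iv in r.t_blocks
                ),
            )
            for c in result.circs
        ),
        out / "circRNAs.bed12",
    )

    if genome_path is not None:
        genome = read_fasta(genome_path)
        introns_df, exons_df, usage_df = analyse_features(
            result.circs, genome, models, config
        )
        introns_df.to_csv(out / "introns.tsv", sep="\t", index=False)
        exons_df.to_csv(out / "novel_exons.tsv", sep="\t", index=False)
        usage_df.to_csv(out / "exon_usage.tsv", sep="\t", index=False)

    if chain_ab_path and chain_ba_path and circs_b is not None:
        pairs, pct_a, pct_b, _ = cons.conserved_circRNAs(
            result.circs, circs_b, read_chain(chain_ab_path), read_chain(chain_ba_path)
        )
        with open(out / "conserved.tsv", "w") as fh:
            fh.write("#circ_a\tcirc_b\n")
            for a, b in pairs:
                fh.write(f"{a.circ_id}\t{b.circ_id}\n")
        result.summary["conserved_pairs"] = len(pairs)
        result.summary["conserved_pct_a"] = round(pct_a, 1)
        result.summary["conserved_pct_b"] = round(pct_b, 1)

    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        for k, v in sorted(result.summary.items()):
            fh.write(f"{k}\t{v}\n")
    stamp.write_text(
        json.dumps({"digest": config.digest(), **asdict(config)}, indent=2)
    )
    return result.summary
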