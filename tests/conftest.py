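"""Shared fixtures: hand-built alignment hits and a seeded simulation."""

from __future__ import annotations

import pytest

from longcirc.bsj_caller import BSJCandidate
from longcirc.formats_io import AlignmentHit
from longcirc.pipeline import PipelineConfig, call_circRNAs
from longcirc.simulator import (
    SimConfig,
    make_reference,
    plant_feature_suite,
    simulate_circ_reads,
)

SIM_SEED = 11


def make_hit(
    read_id="r1",
    q_start=0,
    q_end=None,
    chrom="chr1",
    t_start=1000,
    t_end=None,
    strand="+",
    matches=None,
    mismatches=0,
    q_gap_count=0,
    t_gap_count=0,
    blocks=None,
    q_size=1000,
    t_size=100_000,
):
    """One ungapped single-block hit unless blocks are given explicitly."""
    if t_end is None:
        t_end = t_start + 100
    if q_end is None:
        q_end = q_start + (t_end - t_start)
    if blocks is None:
        blocks = [(q_start, t_start, t_end - t_start)]
    if matches is None:
        matches = sum(ln for _, _, ln in blocks) - mismatches
    return AlignmentHit(
        read_id=read_id,
        q_start=q_start,
        q_end=q_end,
        t_chrom=chrom,
        t_start=t_start,
        t_end=t_end,
        strand=strand,
        matches=matches,
        mismatches=mismatches,
        q_gap_count=q_gap_count,
        t_gap_count=t_gap_count,
        blocks=blocks,
        q_size=q_size,
        t_size=t_size,
    )


def make_candidate(
    read_id="r1",
    chrom="chr1",
    strand="+",
    start=1000,
    end=2000,
    blocks=None,
    bp_gene=0,
    bp_exon=0,
    bp_intron=0,
    corrected=True,
):
    """A corrected BSJ candidate whose genomic blocks are given directly."""
    if blocks is None:
        blocks = [(start, end)]
    blocks = sorted(blocks)
    up_blocks = blocks[:1]
    down_blocks = blocks[1:] or blocks[:1]

    def hit(ivs, q0):
        bl = []
        q = q0
        for s, e in ivs:
            bl.append((q, s, e - s))
            q += e - s
        return make_hit(
            read_id=read_id,
            q_start=q0,
            q_end=q,
            chrom=chrom,
            t_start=min(s for s, _ in ivs),
            t_end=max(e for _, e in ivs),
            strand=strand,
            blocks=bl,
        )

    up = hit(up_blocks, 0)
    down = hit(down_blocks, up.q_end)
    cand = BSJCandidate(
        read_id=read_id,
        t_chrom=chrom,
        strand=strand,
        circ_start=start,
        circ_end=end,
        upstream_hit=up,
        downstream_hit=down,
        score_left=up.matches,
        score_right=down.matches,
        bp_gene=bp_gene,
        bp_exon=bp_exon,
        bp_intron=bp_intron,
        corrected=corrected,
    )
    return cand


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=SIM_SEED)


@pytest.fixture(scope="session")
def sim_reference(sim_config):
    return plant_feature_suite(make_reference(sim_config))


@pytest.fixture(scope="session")
def sim_data(sim_config, sim_reference):
    reads, hits, truth = simulate_circ_reads(sim_config, sim_reference)
    return reads, hits, truth


@pytest.fixture(scope="session")
def sim_call(sim_reference, sim_data):
    reads, hits, _ = sim_data
    return call_circRNAs(
        hits,
        sim_reference.genes,
        sim_reference.known,
        PipelineConfig(),
        {r.read_id for r in reads},
    )
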