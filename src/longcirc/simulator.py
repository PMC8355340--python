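"""Synthetic references and long reads for end-to-end pipeline testing.

Generates a toy genome with multi-exon genes (canonical GT..AG introns),
circRNA isoform sets exhibiting every phenomenon the pipeline must detect
(retained introns, unique and cryptic novel exons, microexons, in-frame
stop exons), once-nicked fragments of circular templates, rolling-RT
concatemers, a per-base quality model, and the PSL hits an ideal aligner
would report — plus a ground-truth record for every emitted read.

Everything is driven by one integer seed: a fixed seed yields byte-identical
FASTQ, PSL and truth output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .formats_io import (
    AlignmentHit,
    Chain,
    ChainMap,
    GeneModel,
    KnownCircRecord,
    LongRead,
    write_chain,
    write_fasta,
    write_fastq,
    write_gene_models,
    write_known_circs,
    write_psl,
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Simulation conditions.

    The defaults emulate a clean nicked-circRNA run: ten multi-exon loci,
    depth 30 per isoform, exactly one nick per molecule at a uniform
    position, no concatemers and no sequencing error (error and end-noise
    knobs switch on the noisy presets).  ``mean_quality`` sets the centre of
    the per-base Phred model (normal, clipped to [2, 40]).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 20_000
    genes_per_chrom: int = 5
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (100, 250)
    intron_len: tuple[int, int] = (150, 400)
    depth: int = 30
    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    end_noise_bp: int = 0
    concatemer_fraction: float = 0.0
    concatemer_rounds: tuple[float, float] = (2.0, 3.0)
    mean_quality: float = 12.0
    quality_sd: float = 3.0
    known_fraction: float = 0.7
    assembly_shift: int = 1_000
    size_weighted_sampling: bool = False

    def validate(self) -> None:
        for name in (
            "mismatch_rate", "insertion_rate", "deletion_rate",
            "concatemer_fraction", "known_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        min_gene = (
            self.exons_per_gene[0] * self.exon_len[0]
            + (self.exons_per_gene[0] - 1) * self.intron_len[0]
        )
        span_needed = self.genes_per_chrom * (
            self.exons_per_gene[1] * self.exon_len[1]
            + (self.exons_per_gene[1] - 1) * self.intron_len[1]
            + 200
        )
        if span_needed > self.chrom_len:
            raise ValueError(
                f"genes do not fit: need ~{span_needed} bp per chromosome, "
                f"have {self.chrom_len}"
            )
        if min_gene <= 0:
            raise ValueError("degenerate gene geometry")


@dataclass
class CircIsoform:
    isoform_id: str
    blocks: list[tuple[int, int]]  # genomic intervals, ascending
    depth: int
    features: list[str] = field(default_factory=list)

    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class CircDef:
    circ_id: str
    gene_id: str
    t_chrom: str
    strand: str
    start: int
    end: int
    isoforms: list[CircIsoform]


@dataclass
class TruthRecord:
    read_id: str
    circ_id: str
    isoform_id: str
    nick: int
    rounds: float
    n_hits: int
    features: list[str]


@dataclass
class Reference:
    config: SimConfig
    genome: dict[str, str]
    genome_b: dict[str, str]
    genes: list[GeneModel]
    circs: list[CircDef]
    known: list[KnownCircRecord]
    chains_ab: ChainMap
    chains_ba: ChainMap
    planted: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _edit(genome: dict[str, str], chrom: str, pos: int, repl: str) -> None:
    seq = genome[chrom]
    genome[chrom] = seq[:pos] + repl + seq[pos + len(repl) :]


def _force_intron_flanks(genome: dict[str, str], model: GeneModel) -> None:
    """Give every intron canonical splice dinucleotides in transcript sense:
    GT..AG for '+' genes, genomic CT..AC for '-' genes."""
    for s, e in model.introns:
        if model.strand == "+":
            _edit(genome, model.t_chrom, s, "GT")
            _edit(genome, model.t_chrom, e - 2, "AG")
        else:
            _edit(genome, model.t_chrom, s, "CT")
            _edit(genome, model.t_chrom, e - 2, "AC")


def _assign_phases(model: GeneModel) -> None:
    """Entry phase per exon, propagated in transcript order from phase 0."""
    exons = model.exons if model.strand == "+" else list(reversed(model.exons))
    phase = 0
    phases_t = []
    for s, e in exons:
        phases_t.append(phase)
        phase = (phase + (e - s)) % 3
    model.coding_phases = (
        phases_t if model.strand == "+" else list(reversed(phases_t))
    )


def make_reference(config: SimConfig) -> Reference:
    """Build genome, gene models, circRNA definitions, known catalog and a
    coordinate-shifted second assembly with liftover chains both ways."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    circs: list[CircDef] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        genome[chrom] = _random_seq(rng, config.chrom_len)
        cursor = 200
        for gi in range(config.genes_per_chrom):
            idx = ci * config.genes_per_chrom + gi
            strand = "+" if idx % 2 == 0 else "-"
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exons: list[tuple[int, int]] = []
            pos = cursor
            for ei in range(n_exons):
                elen = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
                exons.append((pos, pos + elen))
                pos += elen
                if ei < n_exons - 1:
                    pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            model = GeneModel(
                gene_id=f"gene{idx + 1}", t_chrom=chrom, strand=strand, exons=exons
            )
            _force_intron_flanks(genome, model)
            _assign_phases(model)
            genes.append(model)
            cursor = pos + 200
            # one circRNA per gene spanning all its exons
            circ = CircDef(
                circ_id=f"circ{idx + 1}",
                gene_id=model.gene_id,
                t_chrom=chrom,
                strand=strand,
                start=exons[0][0],
                end=exons[-1][1],
                isoforms=[
                    CircIsoform(
                        isoform_id=f"circ{idx + 1}.iso1",
                        blocks=list(exons),
                        depth=config.depth,
                    )
                ],
            )
            circs.append(circ)

    known: list[KnownCircRecord] = []
    dbs = ("circbase", "circatlas", "circpedia")
    for i, circ in enumerate(circs):
        if rng.random() < config.known_fraction:
            for j, db in enumerate(dbs):
                if (i + j) % 2 == 0:  # deterministic spread over catalogs
                    known.append(
                        KnownCircRecord(
                            db_name=db,
                            circ_id=f"{db[:2]}_{i + 1:04d}",
                            t_chrom=circ.t_chrom,
                            start=circ.start,
                            end=circ.end,
                            strand=circ.strand,
                        )
                    )

    shift = config.assembly_shift
    genome_b = {
        chrom: _random_seq(rng, shift) + seq for chrom, seq in genome.items()
    }
    chains_ab = ChainMap(
        [
            Chain(
                score=1000,
                t_name=chrom, t_size=len(seq), t_start=0, t_end=len(seq),
                q_name=chrom, q_size=len(seq) + shift, q_strand="+",
                q_start=shift, q_end=len(seq) + shift,
                blocks=[(len(seq), 0, 0)],
                chain_id=i + 1,
            )
            for i, (chrom, seq) in enumerate(genome.items())
        ]
    )
    chains_ba = ChainMap(
        [
            Chain(
                score=1000,
                t_name=chrom, t_size=len(seq) + shift, t_start=shift,
                t_end=len(seq) + shift,
                q_name=chrom, q_size=len(seq), q_strand="+",
                q_start=0, q_end=len(seq),
                blocks=[(len(seq), 0, 0)],
                chain_id=i + 1,
            )
            for i, (chrom, seq) in enumerate(genome.items())
        ]
    )
    return Reference(
        config=config,
        genome=genome,
        genome_b=genome_b,
        genes=genes,
        circs=circs,
        known=known,
        chains_ab=chains_ab,
        chains_ba=chains_ba,
    )


# ---------------------------------------------------------------------------
# feature planting
# ---------------------------------------------------------------------------

def _plant_exon(
    genome: dict[str, str],
    chrom: str,
    start: int,
    strand: str,
    transcript_seq: str,
) -> tuple[int, int]:
    """Write an exon with canonical splice flanks into the genome.

    ``transcript_seq`` is the exon in transcript orientation; the genomic
    copy is reverse-complemented for '-' strand.  Flanking dinucleotides are
    set so the AG-exon-GT signature holds in transcript orientation.
    """
    end = start + len(transcript_seq)
    body = transcript_seq if strand == "+" else revcomp(transcript_seq)
    _edit(genome, chrom, start, body)
    if strand == "+":
        _edit(genome, chrom, start - 2, "AG")
        _edit(genome, chrom, end, "GT")
    else:
        _edit(genome, chrom, start - 2, "AC")
        _edit(genome, chrom, end, "CT")
    return start, end


def _novel_exon_isoforms(
    circ: CircDef, interval: tuple[int, int], depth: int, tag: str
) -> None:
    base = circ.isoforms[0]
    blocks = sorted(base.blocks + [interval])
    circ.isoforms = [
        replace(base, depth=depth),
        CircIsoform(
            isoform_id=f"{circ.circ_id}.iso2",
            blocks=blocks,
            depth=depth,
            features=[tag],
        ),
    ]


def _stop_free(n: int) -> str:
    return ("GCA" * (n // 3 + 1))[:n]


def plant_feature_suite(reference: Reference) -> Reference:
    """Plant one instance of each splicing phenomenon into the reference.

    Uses the first seven circRNAs: fully retained intron, partially
    retained intron, unique novel exon (60 nt), cryptic exon extending an
    annotated exon by 25 nt at its transcript-5' side, microexons of 12 and
    20 nt, and a 9-nt in-frame exon carrying a stop codon in the dictated
    phase.  Planted coordinates are recorded in ``reference.planted`` for
    oracle tests.
    """
    circs = reference.circs
    genes = {m.gene_id: m for m in reference.genes}
    if len(circs) < 7:
        raise ValueError("feature suite needs at least 7 circRNAs")
    genome = reference.genome
    depth = reference.config.depth
    planted = reference.planted

    def intron_of(circ: CircDef, k: int = 0) -> tuple[int, int]:
        exons = circ.isoforms[0].blocks
        if len(exons) < 2:
            raise ValueError(f"{circ.circ_id} has a single exon")
        return exons[k][1], exons[k + 1][0]

    # 1. fully retained intron: every read keeps intron 0
    circ = circs[0]
    s, e = intron_of(circ)
    base = circ.isoforms[0]
    merged = [(base.blocks[0][0], base.blocks[1][1])] + base.blocks[2:]
    circ.isoforms = [
        CircIsoform(
            isoform_id=f"{circ.circ_id}.iso1",
            blocks=merged,
            depth=depth,
            features=["retained_intron"],
        )
    ]
    planted["retained_intron"] = {
        "circ_id": circ.circ_id, "intron": (s, e), "mode": "full",
    }

    # 2. partially retained intron: half the molecules keep intron 0
    circ = circs[1]
    s, e = intron_of(circ)
    base = circ.isoforms[0]
    merged = [(base.blocks[0][0], base.blocks[1][1])] + base.blocks[2:]
    circ.isoforms = [
        replace(base, depth=depth // 2),
        CircIsoform(
            isoform_id=f"{circ.circ_id}.iso2",
            blocks=merged,
            depth=depth - depth // 2,
            features=["partial_retained_intron"],
        ),
    ]
    planted["partial_retained_intron"] = {
        "circ_id": circ.circ_id, "intron": (s, e), "mode": "partial",
    }

    def plant_internal(circ: CircDef, seq: str, tag: str) -> tuple[int, int]:
        s, e = intron_of(circ)
        mid = (s + e) // 2
        start = mid - len(seq) // 2
        if start - 2 <= s or start + len(seq) + 2 >= e:
            raise ValueError(f"intron of {circ.circ_id} too small for planting")
        iv = _plant_exon(genome, circ.t_chrom, start, circ.strand, seq)
        _novel_exon_isoforms(circ, iv, depth, tag)
        planted[tag] = {"circ_id": circ.circ_id, "interval": iv}
        return iv

    # 3. unique novel exon, 60 nt
    plant_internal(circs[2], _stop_free(60), "unique_novel_exon")

    # 4. cryptic exon: 25-nt transcript-5' extension sharing the 3' splice site
    circ = circs[3]
    model = genes[circ.gene_id]
    exons = circ.isoforms[0].blocks
    if circ.strand == "+":
        anchor = exons[1]  # has an upstream intron inside the circ
        ext_start = anchor[0] - 25
        iv = (ext_start, anchor[1])
        _edit(genome, circ.t_chrom, ext_start, _stop_free(25))
        _edit(genome, circ.t_chrom, ext_start - 2, "AG")
        # 3' flank (GT) already present after the annotated exon
    else:
        anchor = exons[-2]
        iv = (anchor[0], anchor[1] + 25)
        _edit(genome, circ.t_chrom, anchor[1], revcomp(_stop_free(25)))
        _edit(genome, circ.t_chrom, anchor[1] + 25, "CT")
        # transcript-3' flank (genomic AC at iv start side) already present
    blocks = [iv if b == anchor else b for b in exons]
    base = circ.isoforms[0]
    circ.isoforms = [
        replace(base, depth=depth),
        CircIsoform(
            isoform_id=f"{circ.circ_id}.iso2",
            blocks=blocks,
            depth=depth,
            features=["cryptic_novel_exon"],
        ),
    ]
    planted["cryptic_novel_exon"] = {
        "circ_id": circ.circ_id, "interval": iv, "annotated": anchor,
    }

    # 5 & 6. microexons of 12 and 20 nt
    plant_internal(circs[4], "GCTGCAGCTGCA", "microexon_12")
    plant_internal(circs[5], "GC" * 10, "microexon_20")

    # 7. 9-nt in-frame exon with a stop codon in the dictated phase
    circ = circs[6]
    model = genes[circ.gene_id]
    s, e = intron_of(circ)
    mid = (s + e) // 2
    start = mid - 4
    from .splice_features import upstream_phase

    probe = (start, start + 9)
    phase = upstream_phase(probe, model)
    offset = (3 - (phase or 0)) % 3
    seq = (_stop_free(offset) + "TAA" + _stop_free(9))[:9]
    iv = _plant_exon(genome, circ.t_chrom, start, circ.strand, seq)
    _novel_exon_isoforms(circ, iv, depth, "stop_exon")
    planted["stop_exon"] = {
        "circ_id": circ.circ_id, "interval": iv, "phase": phase,
    }

    # keep the shifted assembly identical in sequence to the edited genome
    shift = reference.config.assembly_shift
    reference.genome_b = {
        chrom: reference.genome_b[chrom][:shift] + genome[chrom]
        for chrom in genome
    }
    return reference


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _isoform_sequence(genome: dict[str, str], circ: CircDef, iso: CircIsoform) -> str:
    if circ.strand == "+":
        return "".join(genome[circ.t_chrom][s:e] for s, e in iso.blocks)
    return "".join(
        revcomp(genome[circ.t_chrom][s:e]) for s, e in reversed(iso.blocks)
    )


def _transcript_blocks(circ: CircDef, iso: CircIsoform) -> list[tuple[int, int, int]]:
    """(transcript_offset, genomic_start, length) in transcript order."""
    blocks = iso.blocks if circ.strand == "+" else list(reversed(iso.blocks))
    out = []
    off = 0
    for s, e in blocks:
        out.append((off, s, e - s))
        off += e - s
    return out


def _pass_hit(
    read_id: str,
    circ: CircDef,
    tblocks: list[tuple[int, int, int]],
    t_a: int,
    t_b: int,
    q_base: int,
    q_size: int,
    t_size: int,
) -> AlignmentHit:
    """Build the hit an ideal aligner reports for transcript interval [t_a, t_b)."""
    blocks: list[tuple[int, int, int]] = []
    for toff, gs, ln in tblocks:
        a = max(t_a, toff)
        b = min(t_b, toff + ln)
        if a >= b:
            continue
        q = q_base + (a - t_a)
        if circ.strand == "+":
            g = gs + (a - toff)
        else:
            g = gs + (toff + ln - b)
        blocks.append((q, g, b - a))
    blocks.sort(key=lambda blk: blk[1])
    t_start = min(g for _, g, _ in blocks)
    t_end = max(g + ln for _, g, ln in blocks)
    total = sum(ln for _, _, ln in blocks)
    return AlignmentHit(
        read_id=read_id,
        q_start=q_base,
        q_end=q_base + (t_b - t_a),
        t_chrom=circ.t_chrom,
        t_start=t_start,
        t_end=t_end,
        strand=circ.strand,
        matches=total,
        mismatches=0,
        q_gap_count=0,
        t_gap_count=0,
        blocks=blocks,
        q_size=q_size,
        t_size=t_size,
    )


def _apply_mismatches(
    rng: np.random.Generator, seq: list[str], hits: list[AlignmentHit], rate: float
) -> None:
    if rate <= 0:
        return
    bases = "ACGT"
    for hit in hits:
        for q, _, ln in hit.blocks:
            n_err = rng.binomial(ln, rate)
            if n_err == 0:
                continue
            positions = rng.choice(ln, size=n_err, replace=False)
            for pos in sorted(positions):
                i = q + int(pos)
                old = seq[i]
                seq[i] = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4]
            hit.matches -= n_err
            hit.mismatches += n_err


def _trim_ends(hit: AlignmentHit, left: int, right: int) -> AlignmentHit | None:
    """Shave bases off a hit's outer genomic ends (ragged-end noise)."""
    blocks = sorted(hit.blocks, key=lambda b: b[1])
    if left > 0:
        q, g, ln = blocks[0]
        if ln <= left:
            return None
        blocks[0] = (
            (q + left, g + left, ln - left) if hit.strand == "+" else (q, g + left, ln - left)
        )
    if right > 0:
        q, g, ln = blocks[-1]
        if ln <= right:
            return None
        blocks[-1] = (
            (q, g, ln - right) if hit.strand == "+" else (q + right, g, ln - right)
        )
    trimmed = left + right
    hit.blocks = blocks
    hit.t_start = min(g for _, g, _ in blocks)
    hit.t_end = max(g + ln for _, g, ln in blocks)
    hit.q_start = min(q for q, _, _ in blocks)
    hit.q_end = max(q + ln for q, _, ln in blocks)
    hit.matches -= trimmed
    return hit


def simulate_circ_reads(
    config: SimConfig, reference: Reference
) -> tuple[list[LongRead], list[AlignmentHit], list[TruthRecord]]:
    """Emit reads, ideal-aligner PSL hits, and one truth record per read.

    Per molecule: pick the isoform (depth molecules each), rotate the
    circular sequence to a uniform nick point, optionally extend to a
    rolling-RT concatemer, apply the error model, and derive the PSL hits —
    one per pass over the circle, so an internally nicked molecule yields
    the classic two reversed hits and a concatemer yields three or more.
    """
    rng = np.random.default_rng(config.seed + 1)
    reads: list[LongRead] = []
    hits_out: list[AlignmentHit] = []
    truth: list[TruthRecord] = []
    t_sizes = {c: len(s) for c, s in reference.genome.items()}
    for circ in reference.circs:
        for iso in circ.isoforms:
            iso_seq = _isoform_sequence(reference.genome, circ, iso)
            L = len(iso_seq)
            tblocks = _transcript_blocks(circ, iso)
            for mi in range(iso.depth):
                read_id = f"{iso.isoform_id}.m{mi + 1}"
                nick = int(rng.integers(0, L))
                if config.concatemer_fraction > 0 and rng.random() < config.concatemer_fraction:
                    rounds = float(rng.uniform(*config.concatemer_rounds))
                else:
                    rounds = 1.0
                total = int(round(rounds * L))
                # transcript passes: [nick, L), k x [0, L), [0, residual)
                intervals: list[tuple[int, int]] = []
                remaining = total
                a = nick
                while remaining > 0:
                    b = min(L, a + remaining)
                    intervals.append((a, b))
                    remaining -= b - a
                    a = 0
                seq_chars = list(
                    "".join(iso_seq[a:b] for a, b in intervals)
                )
                q_size = len(seq_chars)
                read_hits = []
                q_base = 0
                for a, b in intervals:
                    read_hits.append(
                        _pass_hit(
                            read_id, circ, tblocks, a, b, q_base, q_size,
                            t_sizes[circ.t_chrom],
                        )
                    )
                    q_base += b - a
                _apply_mismatches(rng, seq_chars, read_hits, config.mismatch_rate)
                if config.end_noise_bp > 0:
                    noisy = []
                    for hit in read_hits:
                        left = int(rng.integers(0, config.end_noise_bp + 1))
                        right = int(rng.integers(0, config.end_noise_bp + 1))
                        t = _trim_ends(hit, left, right)
                        if t is not None:
                            noisy.append(t)
                    read_hits = noisy
                quals = np.clip(
                    np.rint(rng.normal(config.mean_quality, config.quality_sd, q_size)),
                    2, 40,
                ).astype(int)
                reads.append(
                    LongRead(read_id=read_id, sequence="".join(seq_chars), qualities=list(quals))
                )
                hits_out.extend(read_hits)
                truth.append(
                    TruthRecord(
                        read_id=read_id,
                        circ_id=circ.circ_id,
                        isoform_id=iso.isoform_id,
                        nick=nick,
                        rounds=rounds,
                        n_hits=len(read_hits),
                        features=list(iso.features),
                    )
                )
    return reads, hits_out, truth


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tcirc_id\tisoform_id\tnick\trounds\tn_hits\tfeatures\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.circ_id}\t{t.isoform_id}\t{t.nick}\t"
                f"{t.rounds:.3f}\t{t.n_hits}\t{','.join(t.features) or '.'}\n"
            )


def write_simulation(config: SimConfig, out_dir) -> Reference:
    """Run the full generator and write every artifact under ``out_dir``.

    Writes genome.fa, genome_b.fa, genes.tsv, known.bed, reads.fastq,
    truth.psl, truth.tsv, planted.json and chains/ (both directions).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = plant_feature_suite(make_reference(config))
    reads, hits, truth = simulate_circ_reads(config, reference)
    write_fasta(reference.genome, out / "genome.fa")
    write_fasta(reference.genome_b, out / "genome_b.fa")
    write_gene_models(reference.genes, out / "genes.tsv")
    write_known_circs(reference.known, out / "known.bed")
    write_fastq(reads, out / "reads.fastq")
    write_psl(hits, out / "truth.psl")
    write_truth(truth, out / "truth.tsv")
    (out / "chains").mkdir(exist_ok=True)
    write_chain(reference.chains_ab, out / "chains" / "a_to_b.chain")
    write_chain(reference.chains_ba, out / "chains" / "b_to_a.chain")
    with open(out / "planted.json", "w") as fh:
        json.dump(
            {k: {kk: list(vv) if isinstance(vv, tuple) else vv for kk, vv in d.items()}
             for k, d in reference.planted.items()},
            fh, indent=2, sort_keys=True,
        )
    return reference
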