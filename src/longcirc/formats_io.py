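"""Readers, writers and sequence utilities shared across the pipeline.

All coordinates are 0-based half-open on the forward genome strand, the
convention shared by PSL and BED.  Alignments travel as PSL (BLAT's native
21-column format); circRNA isoforms are emitted as BED12; gene models are a
refFlat-like tab table; known-circRNA catalogs are BED-like tab tables;
assembly-to-assembly maps are UCSC chain files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

PSL_COLUMNS = 21

PSL_HEADER = (
    "psLayout version 3\n"
    "\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        "
    "\tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes "
    "\tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     "
    "\tsize\tstart\tend\tname     \tsize\tstart\tend\tcount\n"
    + "-" * 160 + "\n"
)


class PslParseError(ValueError):
    """A PSL line that does not satisfy the 21-column BLAT layout."""


class FastqParseError(ValueError):
    """A FASTQ record that cannot be parsed."""


# ---------------------------------------------------------------------------
# quality arithmetic
# ---------------------------------------------------------------------------

def q_to_error(q: float) -> float:
    """Convert a Phred quality score to a per-base error probability.

    Phred scores are defined as Q = -10*log10(err); inverting gives
    err = 10^(-Q/10).  Q=10 is a 10% error rate, Q=0 certainty of error.

    Parameters
    ----------
    q : float
        Phred score, finite and >= 0.
    """
    if not math.isfinite(q) or q < 0:
        raise ValueError(f"Phred score must be finite and non-negative, got {q!r}")
    return 10.0 ** (-q / 10.0)


def mean_quality(qualities: Sequence[int], method: str = "phred_of_mean_error") -> float:
    """Average read quality on the Phred scale.

    ``phred_of_mean_error`` (default) converts every base to an error
    probability, averages those, and converts back; this is how long-read QC
    tools summarise read accuracy and avoids overweighting high-quality
    bases.  ``mean_phred`` is the plain arithmetic mean of Phred values,
    exposed as an alternative convention.
    """
    qs = np.asarray(qualities, dtype=float)
    if qs.size == 0:
        return 0.0
    if method == "phred_of_mean_error":
        mean_err = np.mean(10.0 ** (-qs / 10.0))
        return float(-10.0 * math.log10(mean_err))
    if method == "mean_phred":
        return float(qs.mean())
    raise ValueError(f"unknown mean-quality method {method!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LongRead:
    """A single long read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def mean_quality(self, method: str = "phred_of_mean_error") -> float:
        return mean_quality(self.qualities, method=method)


@dataclass
class AlignmentHit:
    """One PSL record: a read segment mapped to a genomic interval.

    ``blocks`` are (q_block_start, t_block_start, length) triples sorted by
    genomic position; for minus-strand hits read coordinates have been
    normalised to the forward read orientation, so ascending genomic blocks
    run descending on the read axis.
    """

    read_id: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    strand: str
    matches: int
    mismatches: int
    q_gap_count: int
    t_gap_count: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    q_size: int = 0
    t_size: int = 0

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.t_start < self.t_end):
            raise ValueError(f"hit for {self.read_id}: empty or inverted interval")
        if self.strand not in "+-":
            raise ValueError(f"hit for {self.read_id}: bad strand {self.strand!r}")

    @property
    def t_blocks(self) -> list[tuple[int, int]]:
        """Genomic intervals covered by this hit's blocks."""
        return [(t, t + ln) for _, t, ln in self.blocks]


@dataclass
class GeneModel:
    """One transcript model: ordered exons, derived introns, rRNA flag."""

    gene_id: str
    t_chrom: str
    strand: str
    exons: list[tuple[int, int]]
    is_rRNA: bool = False
    coding_phases: list[int] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s1, e1)} {(s2, e2)}")
        if self.coding_phases is not None and len(self.coding_phases) != len(self.exons):
            raise ValueError(f"{self.gene_id}: phase list does not match exon count")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if e1 < s2
        ]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class KnownCircRecord:
    """A catalog entry (circBase / circAtlas / CIRCpedia style)."""

    db_name: str
    circ_id: str
    t_chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.circ_id}: start >= end")


@dataclass
class Chain:
    """One UCSC chain: colinear ungapped blocks between two assemblies.

    The chain maps *target* (source assembly, always + strand) coordinates to
    *query* (destination assembly) coordinates.  ``blocks`` holds
    (size, dt, dq) rows; the final row has dt = dq = 0.
    """

    score: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]
    chain_id: int = 0

    def aligned_blocks(self) -> Iterator[tuple[int, int, int]]:
        """Yield (t_block_start, q_block_start, size) in chain coordinates.

        q positions are in chain orientation (reverse-complement coordinates
        when q_strand == '-'); callers flip to forward coordinates.
        """
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            yield t, q, size
            t += size + dt
            q += size + dq


@dataclass
class ChainMap:
    """All chains of one assembly-to-assembly liftover file, in file order."""

    chains: list[Chain]

    def for_chrom(self, chrom: str) -> list[Chain]:
        return [c for c in self.chains if c.t_name == chrom]


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[LongRead]:
    """Stream LongReads from a Sanger-encoded (Phred+33) FASTQ file."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield LongRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=rec.letter_annotations["phred_quality"],
            )
    except ValueError as exc:
        raise FastqParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[LongRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def filter_reads(
    reads: Iterable[LongRead],
    min_quality: float = 7.0,
    min_length: int = 250,
    quality_method: str = "phred_of_mean_error",
) -> Iterator[LongRead]:
    """Keep reads with mean quality >= min_quality and length >= min_length.

    Both thresholds are inclusive and order is preserved.  ``quality_method``
    selects the mean-quality convention (see :func:`mean_quality`).
    """
    for read in reads:
        if len(read) >= min_length and read.mean_quality(quality_method) >= min_quality:
            yield read


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

def _split_csv_ints(fieldval: str) -> list[int]:
    return [int(x) for x in fieldval.rstrip(",").split(",") if x != ""]


def parse_psl(lines: Iterable[str], dialect: str = "auto") -> Iterator[AlignmentHit]:
    """Parse a 21-column PSL stream into AlignmentHits.

    ``dialect`` is one of ``headered`` (psLayout 5-line header expected),
    ``headerless``, or ``auto``.  Minus-strand query coordinates (PSL stores
    qStarts of '-' hits in reverse-complement coordinates) are normalised to
    the forward read orientation so every downstream step sees one read axis.
    """
    it = iter(lines)
    lineno = 0
    buffered: list[tuple[int, str]] = []
    if dialect in ("headered", "auto"):
        first = next(it, None)
        lineno += 1
        if first is not None:
            if first.startswith("psLayout"):
                # skip the remaining 4 header lines (blank, 2 column rows, dashes)
                for _ in range(4):
                    next(it, None)
                    lineno += 1
            elif dialect == "headered":
                raise PslParseError("expected psLayout header, none found")
            else:
                buffered.append((lineno, first))
    for lineno, line in buffered + [(lineno + i + 1, ln) for i, ln in enumerate(it)]:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != PSL_COLUMNS:
            raise PslParseError(
                f"line {lineno}: expected {PSL_COLUMNS} columns, got {len(fields)}"
            )
        try:
            matches, mismatches = int(fields[0]), int(fields[1])
            q_gap_count, t_gap_count = int(fields[4]), int(fields[6])
            strand = fields[8]
            read_id = fields[9]
            q_size, q_start, q_end = int(fields[10]), int(fields[11]), int(fields[12])
            t_chrom = fields[13]
            t_size, t_start, t_end = int(fields[14]), int(fields[15]), int(fields[16])
            block_count = int(fields[17])
            block_sizes = _split_csv_ints(fields[18])
            q_starts = _split_csv_ints(fields[19])
            t_starts = _split_csv_ints(fields[20])
        except ValueError as exc:
            raise PslParseError(f"line {lineno}: non-numeric field ({exc})") from exc
        if not (len(block_sizes) == len(q_starts) == len(t_starts) == block_count):
            raise PslParseError(
                f"line {lineno}: blockCount {block_count} disagrees with block lists"
            )
        if strand not in ("+", "-"):
            raise PslParseError(f"line {lineno}: bad strand {strand!r}")
        if strand == "-":
            # PSL '-' rows give qStarts on the reverse-complemented read
            q_starts = [q_size - (qs + ln) for qs, ln in zip(q_starts, block_sizes)]
        blocks = sorted(
            zip(q_starts, t_starts, block_sizes), key=lambda b: b[1]
        )
        yield AlignmentHit(
            read_id=read_id,
            q_start=q_start,
            q_end=q_end,
            t_chrom=t_chrom,
            t_start=t_start,
            t_end=t_end,
            strand=strand,
            matches=matches,
            mismatches=mismatches,
            q_gap_count=q_gap_count,
            t_gap_count=t_gap_count,
            blocks=[tuple(b) for b in blocks],
            q_size=q_size,
            t_size=t_size,
        )


def write_psl(hits: Iterable[AlignmentHit], path, header: bool = False) -> None:
    """Write AlignmentHits as 21-column PSL (inverse of :func:`parse_psl`)."""
    with open(path, "w") as fh:
        if header:
            fh.write(PSL_HEADER)
        for hit in hits:
            blocks = sorted(hit.blocks, key=lambda b: b[1])
            sizes = [ln for _, _, ln in blocks]
            q_starts = [q for q, _, _ in blocks]
            t_starts = [t for _, t, _ in blocks]
            if hit.strand == "-":
                q_starts = [hit.q_size - (q + ln) for q, ln in zip(q_starts, sizes)]
            q_bases = max(hit.q_end - hit.q_start - sum(sizes), 0)
            t_bases = max(hit.t_end - hit.t_start - sum(sizes), 0)
            row = [
                hit.matches, hit.mismatches, 0, 0,
                hit.q_gap_count, q_bases, hit.t_gap_count, t_bases,
                hit.strand, hit.read_id, hit.q_size, hit.q_start, hit.q_end,
                hit.t_chrom, hit.t_size, hit.t_start, hit.t_end,
                len(blocks),
                ",".join(map(str, sizes)) + ",",
                ",".join(map(str, q_starts)) + ",",
                ",".join(map(str, t_starts)) + ",",
            ]
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# poly(A)
# ---------------------------------------------------------------------------

def polyA_stretch(sequence: str, k: int = 7) -> bool:
    """True iff the sequence contains a run of >= k consecutive 'A'.

    Internal adenosine stretches make circRNAs vulnerable to accidental
    capture during oligo-dT poly(A) depletion; N never extends a run.
    """
    if k <= 0:
        return True
    run = 0
    for base in sequence.upper():
        if base == "A":
            run += 1
            if run >= k:
                return True
        else:
            run = 0
    return False


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def write_bed12(records, path) -> None:
    """Write (chrom, start, end, name, score, strand, blocks) rows as BED12.

    ``blocks`` is a sorted list of genomic (start, end) intervals; the first
    must begin at ``start`` and the last end at ``end``.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand, blocks in records:
            blocks = sorted(blocks)
            sizes = [e - s for s, e in blocks]
            rel = [s - start for s, _ in blocks]
            if rel[0] != 0 or blocks[-1][1] != end:
                raise ValueError(f"{name}: blocks do not span [start, end)")
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            chrom, start, end, name, score, strand, start, end,
                            "0,0,0", len(blocks),
                            ",".join(map(str, sizes)) + ",",
                            ",".join(map(str, rel)) + ",",
                        ],
                    )
                )
                + "\n"
            )


def read_bed12(path) -> list[tuple]:
    """Read BED12 back into (chrom, start, end, name, score, strand, blocks)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end, name, score, strand = (
                fields[0], int(fields[1]), int(fields[2]), fields[3],
                int(fields[4]), fields[5],
            )
            sizes = _split_csv_ints(fields[10])
            rel = _split_csv_ints(fields[11])
            if len(sizes) != int(fields[9]) or len(rel) != int(fields[9]):
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            if rel and rel[0] != 0:
                raise ValueError(f"{path}:{lineno}: blockStarts must begin at 0")
            blocks = [(start + r, start + r + s) for r, s in zip(rel, sizes)]
            if blocks and blocks[-1][1] != end:
                raise ValueError(f"{path}:{lineno}: last block must end at chromEnd")
            out.append((chrom, start, end, name, score, strand, blocks))
    return out


# ---------------------------------------------------------------------------
# gene models, known-circ catalogs, chains
# ---------------------------------------------------------------------------

def write_gene_models(models: Iterable[GeneModel], path) -> None:
    """refFlat-like tab table: id, chrom, strand, exonStarts, exonEnds, rRNA, phases."""
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\tstrand\texon_starts\texon_ends\tis_rRNA\tphases\n")
        for m in models:
            phases = (
                ",".join(map(str, m.coding_phases)) if m.coding_phases is not None else "."
            )
            fh.write(
                "\t".join(
                    [
                        m.gene_id, m.t_chrom, m.strand,
                        ",".join(str(s) for s, _ in m.exons),
                        ",".join(str(e) for _, e in m.exons),
                        "1" if m.is_rRNA else "0",
                        phases,
                    ]
                )
                + "\n"
            )


def read_gene_models(path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            gene_id, chrom, strand, starts, ends, rrna, phases = fields
            exon_starts = _split_csv_ints(starts)
            exon_ends = _split_csv_ints(ends)
            if len(exon_starts) != len(exon_ends):
                raise ValueError(f"{path}:{lineno}: exon start/end count mismatch")
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    t_chrom=chrom,
                    strand=strand,
                    exons=list(zip(exon_starts, exon_ends)),
                    is_rRNA=rrna == "1",
                    coding_phases=None if phases == "." else _split_csv_ints(phases),
                )
            )
    return models


def write_known_circs(records: Iterable[KnownCircRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.t_chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.circ_id}\t{r.db_name}\n"
            )


def read_known_circs(path, db_name: str | None = None) -> list[KnownCircRecord]:
    """Read a BED-like catalog: chrom, start, end, strand, id[, db]."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns")
            db = fields[5] if len(fields) > 5 else (db_name or "unknown")
            out.append(
                KnownCircRecord(
                    db_name=db,
                    circ_id=fields[4],
                    t_chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[3],
                )
            )
    return out


def write_chain(chains: ChainMap, path) -> None:
    with open(path, "w") as fh:
        for c in chains.chains:
            fh.write(
                f"chain {c.score} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


def read_chain(path) -> ChainMap:
    """Parse a UCSC chain file."""
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise ValueError(f"{path}: chain {header} not terminated by a bare size line")
        chains.append(
            Chain(
                score=int(header[1]),
                t_name=header[2], t_size=int(header[3]),
                t_start=int(header[5]), t_end=int(header[6]),
                q_name=header[7], q_size=int(header[8]), q_strand=header[9],
                q_start=int(header[10]), q_end=int(header[11]),
                blocks=blocks,
                chain_id=int(header[12]) if len(header) > 12 else 0,
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("chain"):
                flush()
                header = line.split()
                if len(header) < 12:
                    raise ValueError(f"{path}:{lineno}: short chain header")
                if header[4] != "+":
                    raise ValueError(f"{path}:{lineno}: target strand must be +")
                blocks = []
            else:
                parts = line.split()
                if header is None:
                    raise ValueError(f"{path}:{lineno}: block line outside a chain")
                if len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                else:
                    raise ValueError(f"{path}:{lineno}: malformed block line")
    flush()
    return ChainMap(chains=chains)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome sequence from a dict-of-strings or a pyfaidx-like object.

    Returns '' when the window falls outside the chromosome.
    """
    if chrom not in genome:
        return ""
    seq = genome[chrom]
    n = len(seq)
    if start < 0 or end > n or start >= end:
        return ""
    return str(seq[start:end]).upper()
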