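"""Intron retention, novel-exon discovery, microexons, usage and frames."""

import pytest

from longcirc.formats_io import GeneModel
from longcirc.splice_features import (
    ExonCategory,
    FrameClass,
    IntronStats,
    MicroexonClass,
    NovelExon,
    call_retained_introns,
    classify_microexon,
    detect_novel_exons,
    exon_frame_analysis,
    exon_usage,
    intron_coverage,
    linear_inclusion,
    similarity,
    upstream_phase,
)

from conftest import make_candidate


def make_circ(start=1000, end=2000, chrom="chr1", strand="+"):
    from longcirc.bsj_caller import CircRNA

    return CircRNA(
        t_chrom=chrom, strand=strand, start=start, end=end, n_reads=1,
        host_gene="g1", db_ids={}, mean_bp_gene=0, mean_bp_exon=0,
        mean_bp_intron=0, mean_bp_est=0, adjust_min=0, adjust_max=0,
        adjust_mean=0, is_novel=True,
    )


class TestIntronCoverage:
    INTRON = (1300, 1400)

    def spliced_read(self, i):
        return make_candidate(
            f"r{i}", blocks=[(1000, 1300), (1400, 2000)], bp_gene=900, bp_intron=0
        )

    def retaining_read(self, i):
        return make_candidate(
            f"r{i}", blocks=[(1000, 1650), (1650, 2000)], bp_gene=1000, bp_intron=100
        )

    def test_all_reads_splice_intron_out(self):
        reads = [self.spliced_read(i) for i in range(20)]
        (st,) = intron_coverage(make_circ(), reads, [self.INTRON])
        assert st.intron_coverage_fraction == 0.0
        assert st.intronic_fraction == 0.0
        assert st.n_bsj_reads_spanning == 20

    def test_full_retention_arithmetic(self):
        # every read retains a 100-bp intron within a 400-bp gene-mapped span
        reads = [
            make_candidate(
                f"r{i}", blocks=[(1000, 1350), (1350, 1400)],
                start=1000, end=1400, bp_gene=400, bp_intron=100,
            )
            for i in range(10)
        ]
        (st,) = intron_coverage(
            make_circ(start=1000, end=1400), reads, [self.INTRON]
        )
        assert st.intron_coverage_fraction == 1.0
        assert st.intronic_fraction == pytest.approx(0.25)

    def test_half_retention_halves_the_fraction(self):
        # brute-force per-base expectation on constructed reads
        reads = [self.retaining_read(i) for i in range(10)] + [
            self.spliced_read(10 + i) for i in range(10)
        ]
        (st,) = intron_coverage(make_circ(), reads, [self.INTRON])
        full = intron_coverage(
            make_circ(), [self.retaining_read(i) for i in range(20)], [self.INTRON]
        )[0]
        assert st.intron_coverage_fraction == 1.0
        # per-base expectation: mean intron bp 50, mean gene bp 950
        assert st.intronic_fraction == pytest.approx(50 / 950)
        assert full.intronic_fraction == pytest.approx(100 / 1000)

    def test_no_reads_gives_empty_list(self):
        assert intron_coverage(make_circ(), [], [self.INTRON]) == []


class TestRetainedIntronCalls:
    def stats(self, n=25, cov=0.95, frac=0.05, novel=False):
        return IntronStats(
            circ_id="c", intron=(0, 100), n_bsj_reads_spanning=n,
            intron_coverage_fraction=cov, intronic_fraction=frac,
            has_novel_exon_inside=novel,
        )

    @pytest.mark.parametrize(
        "kwargs, called",
        [
            (dict(), True),
            (dict(n=20), True),              # read gate inclusive
            (dict(n=19), False),
            (dict(cov=0.90), True),          # coverage gate inclusive
            (dict(cov=0.89), False),
            (dict(frac=0.03), False),        # intronic gate strictly above 3%
            (dict(frac=0.031), True),
            (dict(novel=True), False),       # novel exon inside vetoes the call
        ],
    )
    def test_threshold_boundaries(self, kwargs, called):
        out = call_retained_introns([self.stats(**kwargs)])
        assert (len(out) == 1) is called

    def test_monotone_in_each_threshold(self):
        import itertools

        stats = [
            self.stats(n=n, cov=c, frac=f)
            for n, c, f in itertools.product(
                (15, 20, 30), (0.85, 0.9, 1.0), (0.01, 0.04, 0.2)
            )
        ]
        base = {id(s) for s in call_retained_introns(stats)}
        for kwargs in (
            dict(min_reads=25), dict(min_cov=0.95), dict(min_intronic_fraction=0.1)
        ):
            stricter = {id(s) for s in call_retained_introns(stats, **kwargs)}
            assert stricter <= base


class TestNovelExonDetection:
    """A 40-bp exon is planted at [120, 160) with AG/GT flanks."""

    @pytest.fixture
    def genome(self):
        seq = list("C" * 400)
        seq[118:120] = "AG"
        seq[160:162] = "GT"
        # flanks for the constitutive segments used by the reads
        seq[18:20] = "AG"
        seq[80:82] = "GT"
        seq[218:220] = "AG"
        seq[300:302] = "GT"
        return {"chr1": "".join(seq)}

    MODELS = [GeneModel("g1", "chr1", "+", [(20, 80), (220, 300)])]

    def read_with_exon(self, i):
        return make_candidate(
            f"r{i}", start=20, end=300, blocks=[(20, 80), (120, 160), (220, 300)]
        )

    def read_without_exon(self, i):
        return make_candidate(f"r{i}", start=20, end=300, blocks=[(20, 80), (220, 300)])

    def test_two_reads_corroborate_unique_novel(self, genome):
        reads = [self.read_with_exon(0), self.read_with_exon(1)]
        exons = [
            e
            for e in detect_novel_exons(reads, genome, self.MODELS)
            if e.category is not ExonCategory.KNOWN
        ]
        assert [e.interval for e in exons] == [(120, 160)]
        assert exons[0].category is ExonCategory.UNIQUE_NOVEL
        assert exons[0].n_supporting_reads == 2

    def test_single_read_not_reported(self, genome):
        reads = [self.read_with_exon(0), self.read_without_exon(1)]
        exons = detect_novel_exons(reads, genome, self.MODELS)
        assert all(e.interval != (120, 160) for e in exons)

    def test_wrong_flank_not_an_exon(self, genome):
        genome = {"chr1": genome["chr1"][:118] + "AC" + genome["chr1"][120:]}
        reads = [self.read_with_exon(0), self.read_with_exon(1)]
        exons = detect_novel_exons(reads, genome, self.MODELS)
        assert all(e.interval != (120, 160) for e in exons)

    def test_cryptic_extension_shares_one_site(self, genome):
        # segment extending the annotated exon 25 bp at its 5' side
        seq = list(genome["chr1"])
        seq[193:195] = "AG"
        genome = {"chr1": "".join(seq)}
        reads = [
            make_candidate(f"r{i}", start=20, end=300, blocks=[(20, 80), (195, 300)])
            for i in range(2)
        ]
        exons = detect_novel_exons(reads, genome, self.MODELS)
        cryptic = [e for e in exons if e.interval == (195, 300)]
        assert len(cryptic) == 1
        assert cryptic[0].category is ExonCategory.CRYPTIC_NOVEL
        assert not cryptic[0].shares_5prime and cryptic[0].shares_3prime

    def test_small_internal_deletion_merges(self, genome):
        # a 10-bp hole inside the planted exon must not split it
        reads = [
            make_candidate(
                f"r{i}", start=20, end=300,
                blocks=[(20, 80), (120, 135), (145, 160), (220, 300)],
            )
            for i in range(2)
        ]
        exons = detect_novel_exons(reads, genome, self.MODELS)
        assert any(e.interval == (120, 160) for e in exons)

    def test_eleven_bp_gap_does_not_merge(self, genome):
        reads = [
            make_candidate(
                f"r{i}", start=20, end=300,
                blocks=[(20, 80), (120, 134), (145, 160), (220, 300)],
            )
            for i in range(2)
        ]
        exons = detect_novel_exons(reads, genome, self.MODELS)
        assert all(e.interval != (120, 160) for e in exons)

    def test_single_exon_circ_reads_yield_nothing(self, genome):
        # a single-exon circRNA read maps as two partial segments of the same
        # exon; the interior break has no splice flanks, so no exon is called
        reads = [
            make_candidate(
                f"r{i}", start=120, end=160, blocks=[(120, 140), (140, 160)]
            )
            for i in range(2)
        ]
        assert detect_novel_exons(reads, genome, self.MODELS) == []


class TestSimilarity:
    def test_identity(self):
        assert similarity((100, 200), (100, 200)) == 1.0

    def test_same_start_shorter(self):
        assert similarity((100, 200), (100, 195)) == 0.95

    def test_disjoint(self):
        assert similarity((100, 200), (300, 400)) == 0.0

    def test_symmetric(self):
        assert similarity((0, 80), (40, 200)) == similarity((40, 200), (0, 80))


class TestMicroexonClasses:
    @pytest.mark.parametrize(
        "length, cls",
        [
            (2, MicroexonClass.NONE),
            (3, MicroexonClass.ME_3_15),
            (12, MicroexonClass.ME_3_15),
            (15, MicroexonClass.ME_3_15),
            (16, MicroexonClass.ME_16_29),
            (29, MicroexonClass.ME_16_29),
            (30, MicroexonClass.NONE),
            (100, MicroexonClass.NONE),
        ],
    )
    def test_length_boundaries(self, length, cls):
        assert classify_microexon(length) is cls


class TestFrameAnalysis:
    def test_length_not_multiple_of_three_is_out_of_frame(self):
        genome = {"chr1": "A" * 10 + "GCTGCTGCTGCTG" + "A" * 10}
        cls, _ = exon_frame_analysis((10, 23), "+", 0, genome, "chr1")
        assert cls is FrameClass.OUT_FRAME_NO_STOP

    def test_in_frame_stop_codon_in_dictated_phase(self):
        genome = {"chr1": "A" * 10 + "ATGTAAGGC" + "A" * 10}
        cls, unknown = exon_frame_analysis((10, 19), "+", 0, genome, "chr1")
        assert cls is FrameClass.IN_FRAME_STOP and not unknown

    def test_in_frame_clean(self):
        genome = {"chr1": "A" * 10 + "ATGGCCGGC" + "A" * 10}
        cls, _ = exon_frame_analysis((10, 19), "+", 0, genome, "chr1")
        assert cls is FrameClass.IN_FRAME_NO_STOP

    def test_stop_only_counts_in_dictated_phase(self):
        # TAA present but only readable in phase 1, not phase 0
        genome = {"chr1": "A" * 10 + "GTAAGCGCC" + "A" * 10}
        cls0, _ = exon_frame_analysis((10, 19), "+", 0, genome, "chr1")
        cls2, _ = exon_frame_analysis((10, 19), "+", 2, genome, "chr1")
        assert cls0 is FrameClass.IN_FRAME_NO_STOP
        assert cls2 is FrameClass.IN_FRAME_STOP

    def test_minus_strand_reads_reverse_complement(self):
        # revcomp of ATGTAAGGC planted on the forward strand
        genome = {"chr1": "A" * 10 + "GCCTTACAT" + "A" * 10}
        cls, _ = exon_frame_analysis((10, 19), "-", 0, genome, "chr1")
        assert cls is FrameClass.IN_FRAME_STOP

    def test_unknown_phase_scans_all_three(self):
        genome = {"chr1": "A" * 10 + "GTAAGCGCC" + "A" * 10}
        cls, unknown = exon_frame_analysis((10, 19), "+", None, genome, "chr1")
        assert unknown and cls is FrameClass.IN_FRAME_STOP

    def test_upstream_phase_propagates_through_exon_lengths(self):
        model = GeneModel(
            "g1", "chr1", "+", [(0, 10), (100, 130)], coding_phases=[0, 1]
        )
        # exit phase of (100,130) entered at phase 1: (1 + 30) % 3 == 1
        assert upstream_phase((200, 220), model) == 1
        assert upstream_phase((0, 0 + 1), model) is None


class TestExonUsage:
    EXON = (1400, 1500)

    def reads(self, using, spanning):
        out = []
        for i in range(spanning):
            blocks = (
                [(1000, 1500), (1500, 2000)]
                if i < using
                else [(1000, 1400), (1500, 2000)]
            )
            out.append(make_candidate(f"r{i}", blocks=blocks))
        return out

    @pytest.mark.parametrize(
        "using, spanning, level", [(4, 5, 0.80), (16, 50, 0.32), (5, 5, 1.0), (0, 30, 0.0)]
    )
    def test_usage_level(self, using, spanning, level):
        usage = exon_usage(make_circ(), self.reads(using, spanning), self.EXON)
        assert usage.usage_level == pytest.approx(level)

    def test_suppression_gates_10_vs_50(self):
        reads = self.reads(16, 50)
        nick = exon_usage(make_circ(), reads, self.EXON, mode="nick")
        panel = exon_usage(make_circ(), reads, self.EXON, mode="panel")
        assert not nick.suppressed
        assert panel.suppressed  # 16 < 50 in targeted-panel mode

    def test_zero_using_suppressed(self):
        usage = exon_usage(make_circ(), self.reads(0, 30), self.EXON, mode="nick")
        assert usage.usage_level == 0.0 and usage.suppressed

    def test_partial_spans_cannot_witness(self):
        # a read ending inside the exon neither spans nor uses it
        reads = [make_candidate("r0", blocks=[(1000, 1450)], start=1000, end=1450)]
        assert exon_usage(make_circ(), reads, self.EXON) is None


class TestLinearInclusion:
    FLANKS = ((100, 200), (400, 500))
    EXON = (280, 300)

    def make_reads(self, including, spanning):
        spans, blocks = [], []
        for i in range(spanning):
            spans.append((100, 500))
            if i < including:
                blocks.append([(100, 200), (280, 300), (400, 500)])
            else:
                blocks.append([(100, 200), (400, 500)])
        return spans, blocks

    @pytest.mark.parametrize(
        "inc, n, pct", [(4, 116, 3.5), (7, 30, 23.0), (0, 50, 0.0)]
    )
    def test_inclusion_fractions(self, inc, n, pct):
        spans, blocks = self.make_reads(inc, n)
        frac = linear_inclusion(spans, blocks, self.EXON, self.FLANKS)
        # printed precision: 4/116 reads as 3.5%, 7/30 as 23%
        assert 100 * frac == pytest.approx(pct, abs=0.5)

    def test_no_spanning_reads_undefined(self):
        assert linear_inclusion([(0, 150)], [[(0, 150)]], self.EXON, self.FLANKS) is None


@pytest.fixture(scope="module")
def features(sim_reference, sim_call):
    from longcirc.pipeline import PipelineConfig, analyse_features

    return analyse_features(
        sim_call.circs, sim_reference.genome, sim_reference.genes, PipelineConfig()
    )


class TestSimulationOracle:
    """Planted splicing features are recovered with their exact categories."""

    def test_planted_retained_introns_called(self, sim_reference, features):
        introns_df, _, _ = features
        called = {
            (row.intron_start, row.intron_end)
            for row in introns_df[introns_df.retained].itertuples()
        }
        for key in ("retained_intron", "partial_retained_intron"):
            assert tuple(sim_reference.planted[key]["intron"]) in called

    @pytest.mark.parametrize(
        "key, category, me_class",
        [
            ("unique_novel_exon", "unique_novel", "none"),
            ("cryptic_novel_exon", "cryptic_novel", "none"),
            ("microexon_12", "unique_novel", "me_3_15"),
            ("microexon_20", "unique_novel", "me_16_29"),
        ],
    )
    def test_planted_exons_categorised(self, sim_reference, features, key, category, me_class):
        _, exons_df, _ = features
        s, e = sim_reference.planted[key]["interval"]
        rows = exons_df[(exons_df.start == s) & (exons_df.end == e)]
        assert len(rows) == 1
        assert rows.iloc[0].category == category
        assert rows.iloc[0].microexon_class == me_class
        assert rows.iloc[0].n_reads >= 2

    def test_planted_stop_exon_frame(self, sim_reference, features):
        _, exons_df, _ = features
        s, e = sim_reference.planted["stop_exon"]["interval"]
        row = exons_df[(exons_df.start == s) & (exons_df.end == e)].iloc[0]
        assert row.frame_class == "in_frame_stop"

    def test_constitutive_exons_have_usage_one(self, sim_reference, features):
        # circRNAs without alternative isoforms: every annotated exon is used
        _, _, usage_df = features
        alt_circs = {
            d["circ_id"] for d in sim_reference.planted.values() if "circ_id" in d
        }
        by_id = {c.circ_id: c for c in sim_reference.circs}
        for circ_def in sim_reference.circs:
            if circ_def.circ_id in alt_circs:
                continue
            key = f"{circ_def.t_chrom}:{circ_def.start}-{circ_def.end}({circ_def.strand})"
            levels = usage_df[usage_df.circ_id == key].usage_level
            assert len(levels) > 0 and (levels == 1.0).all()
        assert by_id  # sanity
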