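"""Core data model: GTF round-trips, clustering, index and splice motifs."""

import pytest
from hypothesis import given, settings, strategies as st

from refinery.annotation import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    GtfError,
    TranscriptModel,
    canonical_splice_fraction,
    cluster_genes,
    read_gtf,
    write_gtf,
)

from conftest import make_transcript


class TestGenomicInterval:
    def test_rejects_inverted_and_bad_strand(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, "?")

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 0, 100)
        assert a.overlaps(GenomicInterval("chr1", 99, 200))
        assert not a.overlaps(GenomicInterval("chr1", 100, 200))
        assert a.overlap_len(GenomicInterval("chr1", 50, 150)) == 50


class TestTranscriptModel:
    def test_requires_strand_and_exons(self):
        with pytest.raises(ValueError, match="strand"):
            make_transcript("t", [(0, 10)], strand=".")
        with pytest.raises(ValueError):
            TranscriptModel("t", "chr1", "+", ())

    def test_rejects_overlapping_exons(self):
        with pytest.raises(ValueError, match="overlap"):
            make_transcript("t", [(0, 100), (50, 150)])

    def test_derived_structure(self):
        t = make_transcript("t", [(100, 200), (300, 400), (500, 600)])
        assert t.intron_chain == ((200, 300), (400, 500))
        assert t.is_spliced and t.n_exons == 3
        assert t.spliced_length == 300
        mono = make_transcript("m", [(0, 50)])
        assert not mono.is_spliced and mono.introns == ()

    def test_five_three_prime_are_strand_aware(self):
        plus = make_transcript("p", [(100, 200)], "+")
        minus = make_transcript("m", [(100, 200)], "-")
        assert (plus.five_prime(), plus.three_prime()) == (100, 200)
        assert (minus.five_prime(), minus.three_prime()) == (200, 100)


class TestGtfIO:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\t.\texon\t101\t200\t.\t+\t.\ttranscript_id "t1";\n')
        ann = read_gtf(p, "x")
        t = ann.transcript("t1")
        assert (t.exons[0].start, t.exons[0].end) == (100, 200)

    def test_intron_chain_from_two_exon_lines(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\t.\texon\t101\t200\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\t.\texon\t301\t400\t.\t+\t.\ttranscript_id "t1";\n'
        )
        assert read_gtf(p, "x").transcript("t1").intron_chain == ((200, 300),)

    def test_round_trip_identity(self, tmp_path, bundle):
        src = tmp_path / "src.gtf"
        dst = tmp_path / "dst.gtf"
        write_gtf(bundle.references["refA"], src)
        ann1 = read_gtf(src, "a")
        write_gtf(ann1, dst)
        ann2 = read_gtf(dst, "a")
        models1 = {(t.transcript_id, t.strand, t.exons) for t in ann1.transcripts()}
        models2 = {(t.transcript_id, t.strand, t.exons) for t in ann2.transcripts()}
        assert models1 == models2

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\t.\texon\t101\t200\n")
        with pytest.raises(GtfError, match="line 1"):
            read_gtf(p, "x")
        p.write_text('chr1\t.\texon\txx\t200\t.\t+\t.\ttranscript_id "t";\n')
        with pytest.raises(GtfError, match="line 1"):
            read_gtf(p, "x")

    def test_exon_without_transcript_id_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(GtfError, match="transcript_id"):
            read_gtf(p, "x")

    def test_unstranded_transcript_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\t.\texon\t101\t200\t.\t.\t.\ttranscript_id "t";\n')
        with pytest.raises(GtfError, match="unstranded"):
            read_gtf(p, "x")


class TestClusterGenes:
    def test_one_nt_overlap_joins(self):
        t1 = make_transcript("t1", [(0, 100)])
        t2 = make_transcript("t2", [(99, 200)])
        ann = cluster_genes([t1, t2])
        assert len(ann) == 1

    def test_strand_awareness(self):
        t1 = make_transcript("t1", [(0, 100)], "+")
        t2 = make_transcript("t2", [(50, 150)], "-")
        assert len(cluster_genes([t1, t2])) == 2

    def test_abutting_spans_stay_separate(self):
        t1 = make_transcript("t1", [(0, 100)])
        t2 = make_transcript("t2", [(100, 200)])
        assert len(cluster_genes([t1, t2])) == 2

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 200),
                st.integers(1, 80),
                st.sampled_from("+-"),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition_and_order_invariance(self, spans):
        ts = [
            make_transcript(f"t{i}", [(s, s + w)], strand)
            for i, (s, w, strand) in enumerate(spans)
        ]
        ann = cluster_genes(ts)
        members = sorted(t.transcript_id for g in ann for t in g.transcripts)
        assert members == sorted(t.transcript_id for t in ts)  # partition
        rev = cluster_genes(ts[::-1])
        grouping = lambda a: sorted(
            tuple(sorted(t.transcript_id for t in g.transcripts)) for g in a
        )
        assert grouping(ann) == grouping(rev)
        ids = lambda a: [g.gene_id for g in a.genes]
        assert ids(ann) == ids(rev)  # deterministic naming


class TestIntervalIndex:
    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 60), st.sampled_from("+-")),
            min_size=1,
            max_size=15,
        ),
        st.tuples(st.integers(0, 300), st.integers(1, 80)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_query_equals_brute_force(self, spans, query):
        ts = [
            make_transcript(f"t{i}", [(s, s + w)], strand)
            for i, (s, w, strand) in enumerate(spans)
        ]
        ann = cluster_genes(ts)
        qs, qw = query
        hits = {g.gene_id for g in ann.overlapping_genes("chr1", qs, qs + qw)}
        brute = {
            g.gene_id
            for g in ann.genes
            if g.span.start < qs + qw and qs < g.span.end
        }
        assert hits == brute


class TestCanonicalSpliceFraction:
    def _ann(self, t):
        return AnnotationSet("x", [GeneModel("g", [t])])

    def test_plus_strand_gt_ag(self):
        genome = {"chr1": "A" * 10 + "GT" + "A" * 6 + "AG" + "A" * 10}
        t = make_transcript("t", [(0, 10), (20, 30)], "+")
        rep = canonical_splice_fraction(self._ann(t), genome)
        assert rep.fraction_canonical == 1.0
        assert rep.motif_counts == {("GT", "AG"): 1}

    def test_minus_strand_reads_reverse_complement(self):
        # forward-strand intron sequence CT....AC is GT..AG after revcomp
        genome = {"chr1": "A" * 10 + "CT" + "A" * 6 + "AC" + "A" * 10}
        t = make_transcript("t", [(0, 10), (20, 30)], "-")
        rep = canonical_splice_fraction(self._ann(t), genome)
        assert rep.fraction_canonical == 1.0

    def test_no_introns_is_not_applicable(self):
        genome = {"chr1": "A" * 50}
        t = make_transcript("t", [(0, 10)])
        rep = canonical_splice_fraction(self._ann(t), genome)
        assert rep.fraction_canonical is None and rep.n_introns == 0

    def test_intron_beyond_chromosome_errors(self):
        genome = {"chr1": "A" * 25}
        t = make_transcript("t", [(0, 10), (30, 40)])
        with pytest.raises(ValueError):
            canonical_splice_fraction(self._ann(t), genome)
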