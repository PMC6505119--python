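"""Structural class codes, gene status and fused transcripts."""

import numpy as np
import pytest

from refinery.annotation import cluster_genes
from refinery.classify import (
    ClassCode,
    GeneStatus,
    classify_transcript,
    combined_membership,
    detect_fused_transcripts,
)

from conftest import make_transcript
from oracles import brute_classify


def ref_set(*transcripts):
    return cluster_genes(list(transcripts), source_label="ref", gene_prefix="RG")


REF4 = make_transcript(
    "r1", [(1000, 1200), (1700, 1900), (2400, 2600), (3100, 3300)]
)


class TestClassCodes:
    def test_identical_chain_is_equal(self):
        q = make_transcript("q", [(900, 1200), (1700, 1900), (2400, 2600), (3100, 3400)])
        assert classify_transcript(q, ref_set(REF4)).code == "="

    def test_internal_subchain_contained(self):
        q = make_transcript("q", [(1700, 1900), (2400, 2600)])
        assert classify_transcript(q, ref_set(REF4)).code == "c"

    def test_mono_exon_inside_reference_exon_contained(self):
        q = make_transcript("q", [(1720, 1880)])
        assert classify_transcript(q, ref_set(REF4)).code == "c"

    def test_chain_extension(self):
        q = make_transcript(
            "q",
            [(1000, 1200), (1700, 1900), (2400, 2600), (3100, 3300), (3700, 4000)],
        )
        assert classify_transcript(q, ref_set(REF4)).code == "k"

    def test_one_shared_junction_plus_novel_is_j(self):
        q = make_transcript("q", [(1000, 1200), (2400, 2600), (3100, 3300)])
        cc = classify_transcript(q, ref_set(REF4))
        assert cc.code == "j" and cc.ref_transcript_id == "r1"

    def test_exon_overlap_without_junction_is_o(self):
        q = make_transcript("q", [(1100, 1500)])
        assert classify_transcript(q, ref_set(REF4)).code == "o"

    def test_antisense_shared_junction_is_s(self):
        q = make_transcript("q", [(1750, 1900), (2400, 2550)], "-")
        assert classify_transcript(q, ref_set(REF4)).code == "s"

    def test_antisense_exon_overlap_is_x(self):
        q = make_transcript("q", [(1050, 1350)], "-")
        assert classify_transcript(q, ref_set(REF4)).code == "x"

    def test_mono_exon_in_intron_is_i(self):
        q = make_transcript("q", [(1950, 2350)])
        assert classify_transcript(q, ref_set(REF4)).code == "i"

    def test_reference_gene_inside_query_intron_is_y(self):
        tiny = make_transcript("r2", [(5000, 5200)])
        q = make_transcript("q", [(4000, 4500), (6000, 6500)])
        assert classify_transcript(q, ref_set(tiny)).code == "y"

    def test_no_overlap_is_u(self):
        q = make_transcript("q", [(10_000, 10_500)])
        assert classify_transcript(q, ref_set(REF4)).code == "u"

    def test_empty_reference_gives_u(self):
        empty = cluster_genes([], "ref")
        q = make_transcript("q", [(0, 100)])
        assert classify_transcript(q, empty).code == "u"

    def test_known_codes_carry_reference_match(self):
        q = make_transcript("q", [(1000, 1200), (1700, 1900), (2400, 2600), (3100, 3300)])
        cc = classify_transcript(q, ref_set(REF4))
        assert cc.ref_transcript_id == "r1" and cc.ref_gene_id


def _random_transcript(rng, tid, strand=None, grid=10, max_coord=40):
    n_exons = int(rng.integers(1, 4))
    bounds = sorted(rng.choice(max_coord, size=2 * n_exons, replace=False))
    pairs = [(int(bounds[2 * i]) * grid, int(bounds[2 * i + 1]) * grid) for i in range(n_exons)]
    strand = strand or ("+" if rng.integers(2) else "-")
    return make_transcript(tid, pairs, strand)


class TestOracleEquivalence:
    def test_random_models_match_brute_force(self):
        rng = np.random.default_rng(7)
        n_checked = 0
        for trial in range(300):
            refs = [
                _random_transcript(rng, f"r{trial}_{i}")
                for i in range(int(rng.integers(1, 5)))
            ]
            reference = cluster_genes(refs, "ref", gene_prefix=f"R{trial}_")
            q = _random_transcript(rng, f"q{trial}")
            got = classify_transcript(q, reference).code
            want = brute_classify(q, reference)
            assert got == want, (q, [r.exons for r in refs], got, want)
            n_checked += 1
        assert n_checked == 300

    def test_reference_order_invariance(self):
        rng = np.random.default_rng(9)
        for trial in range(40):
            refs = [_random_transcript(rng, f"r{i}") for i in range(4)]
            q = _random_transcript(rng, "q")
            a = classify_transcript(q, cluster_genes(refs, "ref"))
            b = classify_transcript(q, cluster_genes(refs[::-1], "ref"))
            assert a == b


class TestGeneStatus:
    def test_known_from_any_known_code(self):
        assert GeneStatus.from_codes(["=", "u"]).status == "known"
        assert GeneStatus.from_codes(["o"]).status == "known"

    def test_all_u_is_novel_intergenic(self):
        assert GeneStatus.from_codes(["u", "u"]).status == "novel_intergenic"

    def test_i_member_makes_novel_intragenic(self):
        assert GeneStatus.from_codes(["x", "i"]).status == "novel_intragenic"

    def test_combined_membership_labels(self):
        statuses = {
            "refA": GeneStatus.from_codes(["u"]),
            "refB": GeneStatus.from_codes(["="]),
        }
        assert combined_membership(statuses) == "known:refB|novel_intergenic:refA"


class TestFusedTranscripts:
    def test_two_gene_overlap_is_fused(self):
        g1 = make_transcript("r1", [(0, 200), (400, 600)])
        g2 = make_transcript("r2", [(5000, 5200), (5400, 5600)])
        reference = ref_set(g1, g2)
        q = make_transcript("q", [(100, 200), (5000, 5100)])
        fused = detect_fused_transcripts([q], reference)
        assert list(fused) == ["q"] and len(fused["q"]) == 2

    def test_double_overlap_of_one_gene_not_fused(self):
        g1 = make_transcript("r1", [(0, 200), (400, 600)])
        q = make_transcript("q", [(100, 200), (400, 500)])
        assert detect_fused_transcripts([q], ref_set(g1)) == {}

    def test_antisense_overlap_does_not_count(self):
        g1 = make_transcript("r1", [(0, 200)], "+")
        g2 = make_transcript("r2", [(5000, 5200)], "-")
        reference = ref_set(g1, g2)
        q = make_transcript("q", [(100, 200), (5000, 5100)], "+")
        assert detect_fused_transcripts([q], reference) == {}
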