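"""ORF calling, representative selection, NMD 50-nt rule and biotypes."""

import pytest

from refinery.biotype import (
    BiotypeCall,
    classify_biotype,
    final_junction_spliced_position,
    find_orfs,
    gene_biotype,
    select_representative_orf,
    spliced_sequence,
)

from conftest import make_transcript
from oracles import brute_final_junction_position, naive_revcomp


class TestSplicedSequence:
    def test_single_exon_plus(self):
        genome = {"chr1": "ATGTAACCGG"}
        t = make_transcript("t", [(0, 6)])
        assert spliced_sequence(t, genome) == "ATGTAA"

    def test_single_exon_minus_is_revcomp(self):
        genome = {"chr1": "ATGTAACCGG"}
        t = make_transcript("t", [(0, 6)], "-")
        assert spliced_sequence(t, genome) == naive_revcomp("ATGTAA")

    def test_multi_exon_concatenation_matches_per_base_oracle(self):
        genome = {"chr1": "ACGTACGTACGTACGTACGTACGTACGT"}
        for strand in "+-":
            t = make_transcript("t", [(2, 7), (10, 14), (20, 25)], strand)
            per_base = "".join(genome["chr1"][p] for e in t.exons for p in range(e.start, e.end))
            if strand == "-":
                per_base = naive_revcomp(per_base)
            assert spliced_sequence(t, genome) == per_base

    def test_exon_out_of_bounds_errors(self):
        genome = {"chr1": "ACGT"}
        t = make_transcript("t", [(0, 10)])
        with pytest.raises(ValueError):
            spliced_sequence(t, genome)


class TestOrfCalling:
    def test_finds_orf_with_stop(self):
        seq = "CC" + "ATG" + "CAC" * 30 + "TAA" + "CC"
        orfs = find_orfs(seq, min_length=30)
        assert len(orfs) == 1
        orf = orfs[0]
        assert seq[orf.start : orf.start + 3] == "ATG"
        assert seq[orf.end - 3 : orf.end] == "TAA"
        assert orf.length == 96

    def test_orf_without_stop_not_reported(self):
        assert find_orfs("ATG" + "CAC" * 40, min_length=30) == []

    def test_min_length_enforced(self):
        seq = "ATG" + "CAC" * 5 + "TAA"  # 21 nt
        assert find_orfs(seq, min_length=75) == []
        assert len(find_orfs(seq, min_length=21)) == 1

    def test_alternative_start_codons(self):
        seq = "CTG" + "CAC" * 30 + "TAA"
        assert find_orfs(seq, min_length=30) == []
        assert len(find_orfs(seq, frozenset({"ATG", "CTG"}), min_length=30)) == 1


class TestRepresentativeOrf:
    def _orfs(self, lengths):
        out = []
        pos = 0
        for L in lengths:
            out.append(find_orfs("ATG" + "CAC" * ((L - 6) // 3) + "TAA", min_length=10)[0])
            pos += L
        return out

    def test_homology_overrides_length(self):
        orfs = self._orfs([300, 240, 90])
        rep = select_representative_orf(orfs, homology_evalues={2: 1e-30})
        assert rep.length == 240 and rep.homology_score == 1e-30

    def test_no_hits_longest_wins(self):
        orfs = self._orfs([300, 240, 90])
        assert select_representative_orf(orfs).length == 300

    def test_hits_above_cutoff_ignored(self):
        orfs = self._orfs([300, 240, 90])
        rep = select_representative_orf(orfs, homology_evalues={2: 1e-3})
        assert rep.length == 300

    def test_empty_gives_none(self):
        assert select_representative_orf([]) is None


def transcript_with_stop_offset(offset):
    """Two-exon transcript whose only ORF stops ``offset`` nt upstream of
    the final junction (spliced length 600, junction at 400)."""
    t = make_transcript("t", [(0, 400), (1000, 1200)])
    junction = 400
    orf_len = 300
    orf_end = junction - offset
    seq = (
        "C" * (orf_end - orf_len)
        + "ATG"
        + "CAC" * ((orf_len - 6) // 3)
        + "TAA"
        + "C" * (600 - orf_end)
    )
    genome = {"chr1": seq[:400] + "N" * 600 + seq[400:]}
    return t, genome


class TestNmdRule:
    @pytest.mark.parametrize("offset,expected", [(49, "protein_coding"),
                                                 (50, "protein_coding"),
                                                 (51, "NMD"),
                                                 (120, "NMD")])
    def test_strictly_more_than_50_nt(self, offset, expected):
        t, genome = transcript_with_stop_offset(offset)
        assert classify_biotype(t, genome).biotype == expected

    def test_mono_exon_never_nmd(self):
        seq = "C" * 100 + "ATG" + "CAC" * 40 + "TAA" + "C" * 300
        t = make_transcript("t", [(0, len(seq))])
        genome = {"chr1": seq}
        assert classify_biotype(t, genome).biotype == "protein_coding"

    def test_final_junction_position_matches_per_base_oracle(self):
        for strand in "+-":
            t = make_transcript("t", [(0, 120), (200, 350), (500, 620)], strand)
            assert final_junction_spliced_position(t) == brute_final_junction_position(t)
        mono = make_transcript("m", [(0, 100)])
        assert final_junction_spliced_position(mono) is None


class TestNonCodingCalls:
    def test_long_orf_free_transcript_is_lncrna(self):
        genome = {"chr1": "C" * 400}
        t = make_transcript("t", [(0, 150), (200, 350)])
        call = classify_biotype(t, genome)
        assert call.biotype == "lncRNA" and call.representative_orf is None

    def test_short_orf_free_transcript_is_short_noncoding(self):
        genome = {"chr1": "C" * 200}
        t = make_transcript("t", [(0, 150)])
        assert classify_biotype(t, genome).biotype == "short_noncoding"

    def test_200_nt_boundary_is_strict(self):
        genome = {"chr1": "C" * 300}
        exactly200 = make_transcript("t", [(0, 200)])
        assert classify_biotype(exactly200, genome).biotype == "short_noncoding"
        over200 = make_transcript("t", [(0, 201)])
        assert classify_biotype(over200, genome).biotype == "lncRNA"


class TestGeneBiotype:
    def _call(self, biotype):
        if biotype in ("protein_coding", "NMD"):
            orf = find_orfs("ATG" + "CAC" * 30 + "TAA", min_length=10)[0]
            return BiotypeCall(biotype, orf)
        return BiotypeCall(biotype)

    def test_any_coding_member_makes_coding_gene(self):
        calls = [self._call("lncRNA"), self._call("protein_coding")]
        assert gene_biotype(calls) == "protein_coding"

    def test_lncrna_beats_nmd(self):
        calls = [self._call("lncRNA"), self._call("NMD")]
        assert gene_biotype(calls) == "lncRNA"

    def test_nmd_only_gene_is_other(self):
        assert gene_biotype([self._call("NMD")]) == "other"
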