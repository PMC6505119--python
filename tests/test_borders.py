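"""Gene-border extensions, promoter windows and independent validation."""

import math

import pytest

from refinery.annotation import GeneModel, GenomicInterval
from refinery.borders import (
    BedRead,
    CandidateRegionPair,
    Peak,
    PeakSet,
    cage_candidate_regions,
    detect_extension,
    expression_gain,
    promoter_region,
    three_prime_extension_exons,
    validate_3prime,
    validate_5prime,
    validate_chip,
)

from conftest import make_transcript


def gene(gid, pairs, strand="+"):
    return GeneModel(gid, [make_transcript(f"{gid}.t", pairs, strand, gene_id=gid)])


class TestDetectExtension:
    def test_plus_strand_5prime_only(self):
        rec = detect_extension(gene("iso", [(1000, 6000)]), gene("ref", [(1500, 6000)]))
        assert (rec.ext5_len, rec.ext3_len, rec.extension_type) == (500, 0, "5prime_only")

    def test_minus_strand_both_ends(self):
        rec = detect_extension(
            gene("iso", [(1000, 6500)], "-"), gene("ref", [(1500, 6000)], "-")
        )
        assert (rec.ext5_len, rec.ext3_len) == (500, 500)
        assert rec.extension_type == "both"

    def test_identical_spans_none(self):
        rec = detect_extension(gene("iso", [(1000, 6000)]), gene("ref", [(1000, 6000)]))
        assert rec.extension_type == "none"

    def test_strand_mirror_swaps_5_and_3(self):
        plus = detect_extension(gene("i", [(900, 6200)]), gene("r", [(1500, 6000)]))
        minus = detect_extension(
            gene("i", [(900, 6200)], "-"), gene("r", [(1500, 6000)], "-")
        )
        assert (plus.ext5_len, plus.ext3_len) == (minus.ext3_len, minus.ext5_len)

    def test_chrom_strand_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            detect_extension(gene("i", [(0, 100)], "+"), gene("r", [(0, 100)], "-"))


class TestPromoterRegion:
    def test_plus_strand_window(self):
        region = promoter_region(gene("g", [(10_000, 12_000)]))
        assert (region.start, region.end) == (9_500, 10_100)

    def test_minus_strand_mirrored(self):
        region = promoter_region(gene("g", [(18_000, 20_000)], "-"))
        assert (region.start, region.end) == (19_900, 20_500)

    def test_clamped_at_origin(self):
        region = promoter_region(gene("g", [(300, 700)]))
        assert (region.start, region.end) == (0, 400)


class TestChipValidation:
    def _peaks(self, *items):
        return PeakSet([Peak(GenomicInterval("chr1", s, e), mark, sample, sig)
                        for s, e, mark, sample, sig in items])

    def test_promoter_and_body_peaks(self):
        g = gene("g", [(10_000, 11_000), (14_000, 15_000)])
        peaks = self._peaks(
            (9_800, 10_050, "H3K4me3", "s1", True),
            (12_000, 13_000, "H3K36me3", "s1", True),
        )
        v = validate_chip(g, peaks)
        assert v.chip_promoter and v.chip_body and v.all_samples_concordant

    def test_h3k4me3_in_body_does_not_validate_promoter(self):
        g = gene("g", [(10_000, 11_000), (14_000, 15_000)])
        v = validate_chip(g, self._peaks((12_000, 13_000, "H3K4me3", "s1", True)))
        assert not v.chip_promoter and not v.chip_body

    def test_one_bp_overlap_counts_zero_does_not(self):
        g = gene("g", [(10_000, 11_000)])
        # promoter window is [9500, 10100)
        one_bp = self._peaks((9_300, 9_501, "H3K4me3", "s1", True))
        assert validate_chip(g, one_bp).chip_promoter
        abutting = self._peaks((9_300, 9_500, "H3K4me3", "s1", True))
        assert not validate_chip(g, abutting).chip_promoter

    def test_insignificant_peaks_ignored(self):
        g = gene("g", [(10_000, 11_000)])
        v = validate_chip(g, self._peaks((9_800, 10_050, "H3K4me3", "s1", False)))
        assert not v.chip_promoter

    def test_all_samples_concordance(self):
        g = gene("g", [(10_000, 11_000)])
        peaks = self._peaks(
            (9_800, 10_050, "H3K4me3", "s1", True),
            (10_100, 10_900, "H3K36me3", "s1", True),
            (9_800, 10_050, "H3K4me3", "s2", True),
        )
        v = validate_chip(g, peaks)
        assert v.chip_promoter and not v.all_samples_concordant


class TestThreePrimeValidation:
    ISO = [(1000, 2000), (3000, 4500)]
    REF = [(1000, 2000), (3000, 4000)]

    def test_extension_exonic_region(self):
        regions = three_prime_extension_exons(gene("i", self.ISO), gene("r", self.REF))
        assert [(r.start, r.end) for r in regions] == [(4000, 4500)]

    def test_contained_read_validates(self):
        reads = [BedRead(GenomicInterval("chr1", 4100, 4150))]
        v = validate_3prime(gene("i", self.ISO), gene("r", self.REF), reads)
        assert v.applicable and v.validated and v.supporting_reads == 1

    def test_boundary_straddling_read_does_not_support(self):
        reads = [BedRead(GenomicInterval("chr1", 3999, 4040))]
        v = validate_3prime(gene("i", self.ISO), gene("r", self.REF), reads)
        assert v.applicable and not v.validated and v.supporting_reads == 0

    def test_read_exactly_filling_extension_supports(self):
        reads = [BedRead(GenomicInterval("chr1", 4000, 4500))]
        v = validate_3prime(gene("i", self.ISO), gene("r", self.REF), reads)
        assert v.validated

    def test_no_extension_not_applicable(self):
        v = validate_3prime(gene("i", self.REF), gene("r", self.REF), [])
        assert not v.applicable

    def test_containment_matches_per_base_coverage_oracle(self):
        import numpy as np

        rng = np.random.default_rng(5)
        iso, ref = gene("i", self.ISO), gene("r", self.REF)
        regions = three_prime_extension_exons(iso, ref)
        covered = {p for r in regions for p in range(r.start, r.end)}
        for _ in range(200):
            s = int(rng.integers(3900, 4600))
            w = int(rng.integers(10, 80))
            read = BedRead(GenomicInterval("chr1", s, s + w))
            v = validate_3prime(iso, ref, [read])
            assert v.validated == all(p in covered for p in range(s, s + w))


class TestExpressionGain:
    ISO = [(1000, 2000), (3000, 4500)]
    REF = [(1000, 2000), (3000, 4000)]

    def _reads(self, n_shared, n_ext):
        reads = [
            BedRead(GenomicInterval("chr1", 1100 + i * 37, 1150 + i * 37))
            for i in range(n_shared)
        ]
        reads += [
            BedRead(GenomicInterval("chr1", 4050 + i * 60, 4100 + i * 60))
            for i in range(n_ext)
        ]
        return reads

    def test_fold_counts_extension_reads(self):
        g = expression_gain(gene("i", self.ISO), gene("r", self.REF), self._reads(10, 4))
        assert (g.count_ref, g.count_iso) == (10, 14)
        assert g.log2_fold == pytest.approx(math.log2(1.4))

    def test_no_extension_reads_fold_one(self):
        g = expression_gain(gene("i", self.ISO), gene("r", self.REF), self._reads(5, 0))
        assert g.log2_fold == pytest.approx(0.0)

    def test_differing_5prime_ends_excluded(self):
        iso = gene("i", [(900, 2000), (3000, 4500)])
        g = expression_gain(iso, gene("r", self.REF), [])
        assert not g.applicable

    def test_zero_reference_count_flagged(self):
        g = expression_gain(gene("i", self.ISO), gene("r", self.REF), self._reads(0, 3))
        assert g.applicable and g.flagged_undefined and g.log2_fold is None


class TestCageRegions:
    def test_region_arithmetic(self):
        iso = gene("i", [(1000, 6000)])
        ref = gene("r", [(1300, 6000)])
        pair = cage_candidate_regions(iso, ref)
        assert pair.testable and pair.length == 300
        assert (pair.iso_region.start, pair.iso_region.end) == (900, 1100)
        assert (pair.ref_region.start, pair.ref_region.end) == (1200, 1400)

    def test_regions_disjoint_for_positive_length(self):
        for L in (3, 30, 99, 300):
            iso = gene("i", [(1000, 6000)])
            ref = gene("r", [(1000 + L, 6000)])
            pair = cage_candidate_regions(iso, ref)
            assert pair.iso_region.end <= pair.ref_region.start

    def test_minus_strand_mirrored(self):
        iso = gene("i", [(1000, 6300)], "-")
        ref = gene("r", [(1000, 6000)], "-")
        pair = cage_candidate_regions(iso, ref)
        assert (pair.iso_region.start, pair.iso_region.end) == (6200, 6400)
        assert (pair.ref_region.start, pair.ref_region.end) == (5900, 6100)

    def test_degenerate_length_untestable(self):
        iso = gene("i", [(999, 6000)])
        ref = gene("r", [(1000, 6000)])
        pair = cage_candidate_regions(iso, ref)
        assert not pair.testable


class TestCageVerdicts:
    def _pair(self):
        iso = gene("i", [(1000, 6000)])
        ref = gene("r", [(1300, 6000)])
        return cage_candidate_regions(iso, ref)  # iso 900-1100, ref 1200-1400

    def tag(self, pos, unique=True, strand="+"):
        if strand == "+":
            iv = GenomicInterval("chr1", pos, pos + 25, "+")
        else:
            iv = GenomicInterval("chr1", pos - 24, pos + 1, "-")
        return BedRead(iv, "t", unique)

    def test_iso_only(self):
        assert validate_5prime(self._pair(), [self.tag(1010)]) == "iso_only"

    def test_both_is_multiple_promoters(self):
        tags = [self.tag(1010), self.tag(1250)]
        assert validate_5prime(self._pair(), tags) == "both"

    def test_ref_only(self):
        assert validate_5prime(self._pair(), [self.tag(1250)]) == "ref_only"

    def test_gap_tag_testable_but_none(self):
        assert validate_5prime(self._pair(), [self.tag(1150)]) == "none"

    def test_multimapping_tags_untestable(self):
        tags = [self.tag(1010, unique=False), self.tag(1250, unique=False)]
        assert validate_5prime(self._pair(), tags) == "untestable"

    def test_minus_strand_tag_position_is_5prime_base(self):
        # a '-' tag whose 5' base (interval end - 1) falls in the iso region
        assert validate_5prime(self._pair(), [self.tag(1010, strand="-")]) == "iso_only"
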