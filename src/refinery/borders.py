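"""Gene-border extension detection and independent validation.

Long-read gene models frequently extend the annotated termini of known
genes.  For each iso-seq gene paired with its best-match reference gene,
this module measures strand-aware 5' and 3' extensions and validates them
with three orthogonal data types:

* **ChIP-seq peaks** — a significant H3K4me3 peak over the promoter
  window (500 bp upstream to 100 bp downstream of the gene's first exon)
  marks an active transcription start; an H3K36me3 peak over the gene body
  marks transcription through it.
* **3'-RNA-seq reads** — poly(A)-anchored reads whose alignment is 100%
  contained in the exonic part of the 3'-extended region confirm the new
  3' terminus.
* **CAGE tags** — uniquely mapped 5'-end tags falling in candidate
  regions of width 2L/3 centred on the iso-seq and reference gene starts
  (L = length of the extended region) discriminate the two competing 5'
  annotations.

For gene pairs with an identical 5' end but an extended 3' end, the gain
in 3'-read counts attributable to the extension is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

import pandas as pd

from .annotation import GeneModel, GenomicInterval

PROMOTER_UPSTREAM_NT = 500
PROMOTER_DOWNSTREAM_NT = 100

H3K4ME3 = "H3K4me3"
H3K36ME3 = "H3K36me3"


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak call with histone mark, sample id and significance."""

    interval: GenomicInterval
    mark: str
    sample: str
    significant: bool = True


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def samples(self) -> list[str]:
        return sorted({p.sample for p in self.peaks})

    @staticmethod
    def from_bed(path) -> "PeakSet":
        """BED with columns chrom, start, end, mark, sample, significant(0/1)."""
        peaks = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, mark, sample, sig = line.split("\t")[:6]
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, int(start), int(end)),
                        mark,
                        sample,
                        sig.strip() not in ("0", "false", "False"),
                    )
                )
        return PeakSet(peaks)


@dataclass(frozen=True)
class BedRead:
    """A BED6-style aligned read/tag; ``unique`` from the score/name column."""

    interval: GenomicInterval
    name: str = ""
    unique: bool = True


def read_bed6(path) -> list[BedRead]:
    """BED6 where score encodes mapping uniqueness (1=unique, 0=multi)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            unique = (fields[4].strip() not in ("0", "0.0")) if len(fields) > 4 else True
            strand = fields[5] if len(fields) > 5 else "."
            out.append(BedRead(GenomicInterval(chrom, start, end, strand), name, unique))
    return out


@dataclass
class ExtensionRecord:
    """5'/3' border change of an iso-seq gene versus its reference gene."""

    iso_gene_id: str
    ref_gene_id: str
    ref_source: str
    ext5_len: int
    ext3_len: int
    chip_promoter: bool | None = None
    chip_body: bool | None = None
    chip_all_samples: bool | None = None
    three_prime_validated: bool | None = None
    three_prime_read_count: int | None = None
    cage_verdict: str | None = None

    @property
    def extension_type(self) -> str:
        if self.ext5_len > 0 and self.ext3_len > 0:
            return "both"
        if self.ext5_len > 0:
            return "5prime_only"
        if self.ext3_len > 0:
            return "3prime_only"
        return "none"


def detect_extension(
    iso_gene: GeneModel, ref_gene: GeneModel, ref_source: str = ""
) -> ExtensionRecord:
    """Strand-aware extension lengths of ``iso_gene`` beyond ``ref_gene``.

    On '+' the 5' extension is how far the iso start lies left of the
    reference start; on '-' the genomic right end is the 5' end and the
    roles mirror.  Negative (contracted) sides count as 0.
    """
    if iso_gene.chrom != ref_gene.chrom or iso_gene.strand != ref_gene.strand:
        raise ValueError(
            f"cannot pair {iso_gene.gene_id} with {ref_gene.gene_id}: "
            "chromosome/strand mismatch"
        )
    iso, ref = iso_gene.span, ref_gene.span
    left = max(0, ref.start - iso.start)
    right = max(0, iso.end - ref.end)
    if iso_gene.strand == "+":
        ext5, ext3 = left, right
    else:
        ext5, ext3 = right, left
    return ExtensionRecord(
        iso_gene.gene_id, ref_gene.gene_id, ref_source, ext5, ext3
    )


def promoter_region(gene: GeneModel) -> GenomicInterval:
    """Promoter window around the gene's first-exon start (strand-aware TSS):
    500 bp upstream to 100 bp downstream, clamped at the chromosome origin."""
    tss = gene.tss()
    if gene.strand == "+":
        start, end = tss - PROMOTER_UPSTREAM_NT, tss + PROMOTER_DOWNSTREAM_NT
    else:
        start, end = tss - PROMOTER_DOWNSTREAM_NT, tss + PROMOTER_UPSTREAM_NT
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


@dataclass
class ChipVerdict:
    chip_promoter: bool
    chip_body: bool
    per_sample: dict[str, tuple[bool, bool]]

    @property
    def all_samples_concordant(self) -> bool:
        """True iff every sample shows both a promoter and a body peak."""
        return bool(self.per_sample) and all(
            p and b for p, b in self.per_sample.values()
        )


def validate_chip(
    gene: GeneModel, peaks: PeakSet, min_overlap: int = 1
) -> ChipVerdict:
    """Promoter (H3K4me3) and gene-body (H3K36me3) peak support for a gene.

    A verdict is positive when at least one significant peak of the right
    mark overlaps the region by >= ``min_overlap`` bp.
    """
    prom = promoter_region(gene)
    body = gene.span
    per_sample: dict[str, list[bool]] = {}
    for sample in peaks.samples():
        per_sample[sample] = [False, False]
    for p in peaks.peaks:
        if not p.significant:
            continue
        entry = per_sample.setdefault(p.sample, [False, False])
        if p.mark == H3K4ME3 and p.interval.overlap_len(prom) >= min_overlap:
            entry[0] = True
        if p.mark == H3K36ME3 and p.interval.overlap_len(body) >= min_overlap:
            entry[1] = True
    return ChipVerdict(
        chip_promoter=any(v[0] for v in per_sample.values()),
        chip_body=any(v[1] for v in per_sample.values()),
        per_sample={s: (v[0], v[1]) for s, v in per_sample.items()},
    )


def three_prime_extension_exons(
    iso_gene: GeneModel, ref_gene: GeneModel
) -> list[GenomicInterval]:
    """Exonic intervals of the iso gene lying beyond the reference 3' terminus."""
    exonic = iso_gene.exonic_intervals()
    ref = ref_gene.span
    out = []
    for iv in exonic:
        if iso_gene.strand == "+":
            if iv.end > ref.end:
                out.append(
                    GenomicInterval(
                        iv.chrom, max(iv.start, ref.end), iv.end, iv.strand
                    )
                )
        else:
            if iv.start < ref.start:
                out.append(
                    GenomicInterval(
                        iv.chrom, iv.start, min(iv.end, ref.start), iv.strand
                    )
                )
    return out


def _contained_in_regions(
    read: GenomicInterval, regions: Sequence[GenomicInterval]
) -> bool:
    """Read fully covered by the (disjoint, sorted) region list.

    Regions are exon intervals; a read spanning a gap between two regions
    is not contained.
    """
    for r in regions:
        if r.chrom == read.chrom and r.start <= read.start and read.end <= r.end:
            return True
    return False


@dataclass
class ThreePrimeVerdict:
    applicable: bool
    validated: bool
    supporting_reads: int


def validate_3prime(
    iso_gene: GeneModel,
    ref_gene: GeneModel,
    reads: Sequence[BedRead],
) -> ThreePrimeVerdict:
    """3'-read confirmation of a 3' extension.

    A read supports the extension only when 100% of its aligned length is
    covered by the exonic part of the extended region; reads straddling the
    reference 3' boundary do not count.  Not applicable without a 3'
    extension.
    """
    record = detect_extension(iso_gene, ref_gene)
    if record.ext3_len == 0:
        return ThreePrimeVerdict(False, False, 0)
    regions = three_prime_extension_exons(iso_gene, ref_gene)
    n = sum(1 for r in reads if _contained_in_regions(r.interval, regions))
    return ThreePrimeVerdict(True, n >= 1, n)


@dataclass
class ExpressionGain:
    applicable: bool
    count_ref: int
    count_iso: int
    log2_fold: float | None
    flagged_undefined: bool = False


def expression_gain(
    iso_gene: GeneModel,
    ref_gene: GeneModel,
    reads: Sequence[BedRead],
    pseudo_count: int = 0,
) -> ExpressionGain:
    """3'-read count gain from an extended 3' annotation.

    Only gene pairs with the exact same 5' end and a 3' extension qualify.
    Counts reads fully contained in the exonic regions of each model and
    reports log2(count_iso / count_ref); with ``pseudo_count`` = 0 a zero
    reference count is flagged undefined.
    """
    record = detect_extension(iso_gene, ref_gene)
    if record.ext5_len != 0 or record.ext3_len == 0:
        return ExpressionGain(False, 0, 0, None)
    iso_ex = iso_gene.exonic_intervals()
    ref_ex = ref_gene.exonic_intervals()
    count_iso = sum(1 for r in reads if _contained_in_regions(r.interval, iso_ex))
    count_ref = sum(1 for r in reads if _contained_in_regions(r.interval, ref_ex))
    num, den = count_iso + pseudo_count, count_ref + pseudo_count
    if den == 0 or num == 0:
        return ExpressionGain(True, count_ref, count_iso, None, flagged_undefined=True)
    return ExpressionGain(True, count_ref, count_iso, math.log2(num / den))


@dataclass
class CandidateRegionPair:
    """Candidate 5'-end regions of width 2L/3 centred on each gene start."""

    iso_region: GenomicInterval | None
    ref_region: GenomicInterval | None
    length: int
    testable: bool


def cage_candidate_regions(
    iso_gene: GeneModel, ref_gene: GeneModel
) -> CandidateRegionPair:
    """Candidate regions for CAGE discrimination of competing 5' ends.

    With a 5' extension of length L, each gene start gets a region of
    +/- L//3 around it; for L > 0 the regions are disjoint by construction
    (width 2L/3 < separation L).  L < 3 is untestable (degenerate regions).
    """
    record = detect_extension(iso_gene, ref_gene)
    L = record.ext5_len
    if L < 3:
        return CandidateRegionPair(None, None, L, False)
    third = L // 3
    iso_tss, ref_tss = iso_gene.tss(), ref_gene.tss()
    iso_region = GenomicInterval(
        iso_gene.chrom, max(0, iso_tss - third), iso_tss + third, iso_gene.strand
    )
    ref_region = GenomicInterval(
        ref_gene.chrom, max(0, ref_tss - third), ref_tss + third, ref_gene.strand
    )
    return CandidateRegionPair(iso_region, ref_region, L, True)


def tag_position(read: BedRead) -> int:
    """CAGE tag position: the 5'-most aligned base (strand-aware)."""
    iv = read.interval
    return iv.start if iv.strand != "-" else iv.end - 1


CAGE_VERDICTS = ("iso_only", "both", "ref_only", "none", "untestable")


def validate_5prime(
    pair: CandidateRegionPair,
    tags: Sequence[BedRead],
    chrom: str | None = None,
) -> str:
    """CAGE verdict for a competing 5'-end pair.

    Only uniquely mapped tags count.  The pair is testable iff >= 1 unique
    tag falls in the closed span from the iso candidate region to the
    reference candidate region (both regions included); the verdict is then
    which of the two regions the tags hit ('both' = multiple promoters).
    """
    if not pair.testable or pair.iso_region is None or pair.ref_region is None:
        return "untestable"
    span_start = min(pair.iso_region.start, pair.ref_region.start)
    span_end = max(pair.iso_region.end, pair.ref_region.end)
    span_chrom = pair.iso_region.chrom
    in_iso = in_ref = in_span = False
    for tag in tags:
        if not tag.unique or tag.interval.chrom != span_chrom:
            continue
        pos = tag_position(tag)
        if span_start <= pos < span_end:
            in_span = True
            if pair.iso_region.start <= pos < pair.iso_region.end:
                in_iso = True
            if pair.ref_region.start <= pos < pair.ref_region.end:
                in_ref = True
    if not in_span:
        return "untestable"
    if in_iso and in_ref:
        return "both"
    if in_iso:
        return "iso_only"
    if in_ref:
        return "ref_only"
    return "none"


def extension_summary(records: Iterable[ExtensionRecord]) -> pd.DataFrame:
    """Counts and median extension per category, in the layout of the
    study's gene-border-extension table (per reference source)."""
    rows = []
    recs = [r for r in records if r.extension_type != "none"]
    for source in sorted({r.ref_source for r in recs}):
        sub = [r for r in recs if r.ref_source == source]
        for ext_type, label in (
            ("5prime_only", "5' extension only"),
            ("3prime_only", "3' extension only"),
            ("both", "Both ends extended"),
        ):
            group = [r for r in sub if r.extension_type == ext_type]
            if ext_type == "5prime_only":
                med = _median([r.ext5_len for r in group])
                med5, med3 = med, None
            elif ext_type == "3prime_only":
                med = _median([r.ext3_len for r in group])
                med5, med3 = None, med
            else:
                med5 = _median([r.ext5_len for r in group])
                med3 = _median([r.ext3_len for r in group])
            rows.append(
                {
                    "annotation": source,
                    "extension_type": label,
                    "n_genes": len(group),
                    "median_ext5_nt": med5,
                    "median_ext3_nt": med3,
                }
            )
    return pd.DataFrame(rows)


def _median(values: Sequence[int]) -> float | None:
    if not values:
        return None
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0
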