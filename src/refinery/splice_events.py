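"""Alternative-splicing event enumeration from pairs of transcript models.

Six event types are counted — skipped exon (SE), alternative 5'/3' splice
site exons (A5E/A3E), alternative first/last exons (AFE/ALE) and mutually
exclusive exons (MXE) — plus intron retention (IR), which is detected but
excluded from all counts because a retained intron cannot be distinguished
from unspliced pre-mRNA.

Events are defined pairwise between two spliced transcripts of the same
gene, then deduplicated across all pairs by their defining genomic
coordinates.  Strand-awareness is implemented by reflecting minus-strand
exon chains into an oriented coordinate system, running the plus-strand
predicates and reflecting the event coordinates back; under a strand flip
the A5E and A3E labels (and AFE/ALE) therefore swap, as they must.

Candidate genes are genes with at least two spliced transcripts; a gene
with >= 1 non-IR event is an alternatively spliced (AS) gene.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import AnnotationSet, GeneModel, TranscriptModel
from .detection import DetectionMatrix

EVENT_TYPES = ("SE", "A5E", "A3E", "AFE", "ALE", "MXE", "IR")
AS_EVENT_TYPES = ("SE", "A5E", "A3E", "AFE", "ALE", "MXE")  # IR excluded


@dataclass(frozen=True, order=True)
class SpliceEvent:
    """An AS event; identity for deduplication is (gene, type, coords)."""

    gene_id: str
    event_type: str
    coords: tuple[int, ...]
    witnesses: tuple[str, str] = ("", "")

    def key(self) -> tuple:
        return (self.gene_id, self.event_type, self.coords)


def _reflect_chain(exons: Sequence[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    return sorted((k - e, k - s) for s, e in exons)


def _oriented(t: TranscriptModel, k: int) -> list[tuple[int, int]]:
    """Exon intervals in transcription orientation (reflected for '-')."""
    exons = [(e.start, e.end) for e in t.exons]
    return _reflect_chain(exons, k) if t.strand == "-" else exons


def _introns(exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def _plus_strand_events(
    e1: list[tuple[int, int]], e2: list[tuple[int, int]]
) -> list[tuple[str, tuple[int, ...]]]:
    """Event (type, oriented coords) list for two oriented exon chains.

    Pure plus-strand logic: position increases 5'->3'; an exon's right edge
    is its donor side, its left edge its acceptor side.
    """
    events: list[tuple[str, tuple[int, ...]]] = []
    i1, i2 = _introns(e1), _introns(e2)
    iset1, iset2 = set(i1), set(i2)

    def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    # SE: internal exon [b, c) of one chain flanked by introns (a, b), (c, d)
    # while the other chain has the single intron (a, d).
    for ex, introns, other_iset in ((e1, i1, iset2), (e2, i2, iset1)):
        for idx in range(1, len(ex) - 1):
            a = introns[idx - 1][0]
            b, c = ex[idx]
            d = introns[idx][1]
            if (a, d) in other_iset:
                events.append(("SE", (a, b, c, d)))

    # MXE: exons [b1, c1) in one chain and [b2, c2) in the other, mutually
    # non-overlapping, with identical outer flanking sites (a, d).
    for idx1 in range(1, len(e1) - 1):
        a1 = i1[idx1 - 1][0]
        d1 = i1[idx1][1]
        x1 = e1[idx1]
        for idx2 in range(1, len(e2) - 1):
            a2 = i2[idx2 - 1][0]
            d2 = i2[idx2][1]
            x2 = e2[idx2]
            if (a1, d1) == (a2, d2) and not overlaps(x1, x2):
                lo, hi = sorted((x1, x2))
                events.append(("MXE", (a1, *lo, *hi, d1)))

    # A5E / A3E: overlapping exon pairs differing at one boundary with the
    # adjoining intron's far splice site shared.
    for idx1, x1 in enumerate(e1):
        for idx2, x2 in enumerate(e2):
            if not overlaps(x1, x2):
                continue
            # donor side (right edge) differs; downstream acceptor shared
            if x1[1] != x2[1] and idx1 < len(i1) and idx2 < len(i2):
                if i1[idx1][1] == i2[idx2][1]:
                    d_lo, d_hi = sorted((x1[1], x2[1]))
                    events.append(("A5E", (d_lo, d_hi, i1[idx1][1])))
            # acceptor side (left edge) differs; upstream donor shared
            if x1[0] != x2[0] and idx1 > 0 and idx2 > 0:
                if i1[idx1 - 1][0] == i2[idx2 - 1][0]:
                    a_lo, a_hi = sorted((x1[0], x2[0]))
                    events.append(("A3E", (i1[idx1 - 1][0], a_lo, a_hi)))

    # AFE: distinct non-overlapping first exons spliced to a shared acceptor.
    f1, f2 = e1[0], e2[0]
    if i1 and i2 and not overlaps(f1, f2) and i1[0][1] == i2[0][1]:
        lo, hi = sorted((f1, f2))
        events.append(("AFE", (*lo, *hi, i1[0][1])))

    # ALE: distinct non-overlapping last exons reached from a shared donor.
    l1, l2 = e1[-1], e2[-1]
    if i1 and i2 and not overlaps(l1, l2) and i1[-1][0] == i2[-1][0]:
        lo, hi = sorted((l1, l2))
        events.append(("ALE", (i1[-1][0], *lo, *hi)))

    # IR: an intron of one chain fully inside an exon of the other.
    for introns, other_ex in ((i1, e2), (i2, e1)):
        for a, b in introns:
            if any(s <= a and b <= e for s, e in other_ex):
                events.append(("IR", (a, b)))

    return events


def pairwise_events(t1: TranscriptModel, t2: TranscriptModel) -> list[SpliceEvent]:
    """All events distinguishing two spliced transcripts of one gene.

    Raises if the transcripts come from different genes or either is
    mono-exonic.  Event coordinates are genomic; identity is stable under
    argument order.
    """
    if t1.gene_id != t2.gene_id:
        raise ValueError(
            f"transcripts {t1.transcript_id} and {t2.transcript_id} are from "
            f"different genes ({t1.gene_id!r} vs {t2.gene_id!r})"
        )
    if not (t1.is_spliced and t2.is_spliced):
        raise ValueError("pairwise events are defined between spliced transcripts")
    if t1.strand != t2.strand or t1.chrom != t2.chrom:
        raise ValueError("transcripts of one gene must share chrom and strand")

    k = max(t1.end, t2.end) + 1  # reflection pivot for '-' strand
    o1, o2 = _oriented(t1, k), _oriented(t2, k)
    raw = _plus_strand_events(o1, o2)

    witnesses = tuple(sorted((t1.transcript_id, t2.transcript_id)))
    events = []
    for etype, coords in raw:
        if t1.strand == "-":
            # labels computed in transcription orientation are already
            # biological; only the coordinates are mapped back to genomic
            coords = tuple(sorted(k - c for c in coords))
        events.append(SpliceEvent(t1.gene_id, etype, tuple(coords), witnesses))
    # a pair can legitimately produce the same event via one path only;
    # dedup guards against symmetric double-reporting (e.g. SE scanned from
    # both chains can never fire twice, but IR can if chains nest oddly)
    uniq = {}
    for ev in events:
        uniq.setdefault(ev.key(), ev)
    return sorted(uniq.values())


@dataclass
class GeneEventReport:
    gene_id: str
    events: list[SpliceEvent]
    counts: Counter
    ir_events: list[SpliceEvent]

    @property
    def is_as_gene(self) -> bool:
        return len(self.events) > 0

    @property
    def n_events(self) -> int:
        return len(self.events)


def gene_events(
    gene: GeneModel, transcript_ids: Iterable[str] | None = None
) -> GeneEventReport:
    """Deduplicated union of pairwise events over all spliced-transcript pairs.

    ``transcript_ids`` optionally restricts the members considered (e.g. to
    the transcripts detected in one tissue).  Genes with fewer than two
    spliced transcripts are not AS candidates and yield an empty report.
    IR events are reported separately and never counted.
    """
    members = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    if transcript_ids is not None:
        wanted = set(transcript_ids)
        members = [t for t in members if t.transcript_id in wanted]
    spliced = [t for t in members if t.is_spliced]
    seen: dict[tuple, SpliceEvent] = {}
    ir: dict[tuple, SpliceEvent] = {}
    if len(spliced) >= 2:
        for t1, t2 in itertools.combinations(spliced, 2):
            for ev in pairwise_events(t1, t2):
                (ir if ev.event_type == "IR" else seen).setdefault(ev.key(), ev)
    events = sorted(seen.values())
    counts = Counter(ev.event_type for ev in events)
    return GeneEventReport(gene.gene_id, events, counts, sorted(ir.values()))


def catalogue_events(
    catalogue: AnnotationSet,
    matrix: DetectionMatrix | None = None,
    tissue: str | None = None,
) -> dict[str, GeneEventReport]:
    """Per-gene event reports, optionally restricted to one tissue's
    detected transcripts via a detection matrix."""
    reports = {}
    for gene in catalogue.genes:
        tids = None
        if matrix is not None and tissue is not None:
            tids = [
                t.transcript_id
                for t in gene.transcripts
                if matrix.get(t.transcript_id, tissue)
            ]
        reports[gene.gene_id] = gene_events(gene, tids)
    return reports


def candidate_genes(catalogue: AnnotationSet) -> list[str]:
    """Genes with at least two spliced transcripts (AS event candidates)."""
    return [
        g.gene_id
        for g in catalogue.genes
        if sum(1 for t in g.transcripts if t.is_spliced) >= 2
    ]
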