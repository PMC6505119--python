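"""Structural classification of query transcripts against a reference set.

Every query transcript receives exactly one of ten class codes describing
its structural relation to the reference annotation, evaluated in a fixed
precedence order (most specific first, sense before antisense, contained
before intergenic)::

    =  identical intron chain to a same-strand reference transcript
    c  intron chain is a contiguous sub-chain of a same-strand reference
       and the query is exonically contained in it
    k  contains a same-strand reference transcript's full intron chain as a
       contiguous sub-chain and extends it with additional junctions
    j  shares >= 1 splice junction (exact donor and acceptor positions)
       with a same-strand reference transcript
    o  same-strand exonic overlap but no shared junction
    s  shares >= 1 junction position with an opposite-strand reference
    x  opposite-strand exonic overlap, no shared junction
    i  >= 1 query exon fully inside an intron of a reference transcript
    y  a reference gene span lies fully inside an intron of the query
    u  no overlap with any reference gene span

Codes {=, c, k, j, o} make the query's gene a *known* gene; a gene that is
not known but has >= 1 "i" member is *novel intragenic*, otherwise *novel
intergenic*.  A transcript whose exons overlap two or more distinct
same-strand reference genes is a *fused transcript*.

Mono-exonic "=" requires reciprocal exon overlap with a mono-exonic
same-strand reference (default: >= 50% of the shorter model each way).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation import AnnotationSet, GeneModel, GenomicInterval, TranscriptModel

CLASS_PRECEDENCE = ("=", "c", "k", "j", "o", "s", "x", "i", "y", "u")
KNOWN_CODES = frozenset({"=", "c", "k", "j", "o"})


@dataclass(frozen=True)
class ClassCode:
    """A class code plus the best reference match that justified it."""

    code: str
    ref_transcript_id: str = ""
    ref_gene_id: str = ""

    def __post_init__(self) -> None:
        if self.code not in CLASS_PRECEDENCE:
            raise ValueError(f"unknown class code {self.code!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """mono_min_reciprocal_overlap: reciprocal-overlap fraction (of the
    shorter model) for mono-exonic '=' calls."""

    mono_min_reciprocal_overlap: float = 0.5


def _exonic_overlap_len(q: TranscriptModel, r: TranscriptModel) -> int:
    total = 0
    for qe in q.exons:
        for re_ in r.exons:
            total += qe.overlap_len(re_)
    return total


def _is_contiguous_subchain(
    sub: Sequence[tuple[int, int]], chain: Sequence[tuple[int, int]]
) -> bool:
    """True iff ``sub`` appears as a contiguous run inside ``chain``.

    The empty chain is a sub-chain of everything.
    """
    if not sub:
        return True
    n, m = len(sub), len(chain)
    return any(tuple(chain[i : i + n]) == tuple(sub) for i in range(m - n + 1))


def _exonically_contained(q: TranscriptModel, r: TranscriptModel) -> bool:
    """Every query exon base lies within reference exon bases."""
    for qe in q.exons:
        covered = 0
        for re_ in r.exons:
            covered += qe.overlap_len(re_)
        if covered < len(qe):
            return False
    return True


def _match_equal(q: TranscriptModel, r: TranscriptModel, cfg: ClassifierConfig) -> bool:
    if q.is_spliced:
        return r.is_spliced and q.intron_chain == r.intron_chain
    if r.is_spliced:
        return False
    ov = q.span.overlap_len(r.span)
    return ov > 0 and ov >= cfg.mono_min_reciprocal_overlap * min(
        len(q.span), len(r.span)
    )


def _match_contained(q: TranscriptModel, r: TranscriptModel) -> bool:
    return _is_contiguous_subchain(q.intron_chain, r.intron_chain) and _exonically_contained(q, r)


def _match_extends(q: TranscriptModel, r: TranscriptModel) -> bool:
    return (
        r.is_spliced
        and len(q.intron_chain) > len(r.intron_chain)
        and _is_contiguous_subchain(r.intron_chain, q.intron_chain)
    )


def _shared_junctions(q: TranscriptModel, r: TranscriptModel) -> int:
    return len(set(q.intron_chain) & set(r.intron_chain))


def _exon_in_intron(q: TranscriptModel, r: TranscriptModel) -> bool:
    """Some query exon fully inside some intron of the reference transcript."""
    for intr in r.introns:
        for qe in q.exons:
            if intr.start <= qe.start and qe.end <= intr.end:
                return True
    return False


def _gene_in_intron(q: TranscriptModel, ref_gene: GeneModel) -> bool:
    sp = ref_gene.span
    return any(intr.start <= sp.start and sp.end <= intr.end for intr in q.introns)


def classify_transcript(
    query: TranscriptModel,
    reference: AnnotationSet,
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassCode:
    """Assign one of the ten class codes to ``query`` against ``reference``.

    Deterministic: the best reference match is the transcript sharing the
    most junctions, ties broken by longest exonic overlap then smallest id.
    An empty reference (or a chromosome without features) yields "u".
    """
    sp = query.span
    genes = reference.overlapping_genes(query.chrom, sp.start, sp.end, strand=None)
    same = [g for g in genes if g.strand == query.strand]
    anti = [g for g in genes if g.strand != query.strand]

    # same-strand, transcript-level predicates in precedence order
    for code, pred in (
        ("=", lambda r: _match_equal(query, r, config)),
        ("c", lambda r: _match_contained(query, r)),
        ("k", lambda r: _match_extends(query, r)),
    ):
        hits = [
            (t, g)
            for g in same
            for t in g.transcripts
            if pred(t)
        ]
        if hits:
            t, g = min(
                hits,
                key=lambda h: (
                    -_shared_junctions(query, h[0]),
                    -_exonic_overlap_len(query, h[0]),
                    h[0].transcript_id,
                ),
            )
            return ClassCode(code, t.transcript_id, g.gene_id)

    j_hits = [
        (t, g)
        for g in same
        for t in g.transcripts
        if _shared_junctions(query, t) > 0
    ]
    if j_hits:
        t, g = min(
            j_hits,
            key=lambda h: (
                -_shared_junctions(query, h[0]),
                -_exonic_overlap_len(query, h[0]),
                h[0].transcript_id,
            ),
        )
        return ClassCode("j", t.transcript_id, g.gene_id)

    o_hits = [
        (t, g)
        for g in same
        for t in g.transcripts
        if _exonic_overlap_len(query, t) > 0
    ]
    if o_hits:
        t, g = min(
            o_hits,
            key=lambda h: (-_exonic_overlap_len(query, h[0]), h[0].transcript_id),
        )
        return ClassCode("o", t.transcript_id, g.gene_id)

    # antisense: junction positions compared genomically, ignoring strand
    s_hits = [
        (t, g)
        for g in anti
        for t in g.transcripts
        if _shared_junctions(query, t) > 0
    ]
    if s_hits:
        t, g = min(
            s_hits,
            key=lambda h: (-_shared_junctions(query, h[0]), h[0].transcript_id),
        )
        return ClassCode("s", t.transcript_id, g.gene_id)

    x_hits = [
        (t, g)
        for g in anti
        for t in g.transcripts
        if _exonic_overlap_len(query, t) > 0
    ]
    if x_hits:
        t, g = min(
            x_hits,
            key=lambda h: (-_exonic_overlap_len(query, h[0]), h[0].transcript_id),
        )
        return ClassCode("x", t.transcript_id, g.gene_id)

    i_hits = [
        (t, g)
        for g in genes
        for t in g.transcripts
        if _exon_in_intron(query, t)
    ]
    if i_hits:
        t, g = min(i_hits, key=lambda h: h[0].transcript_id)
        return ClassCode("i", t.transcript_id, g.gene_id)

    y_hits = [g for g in genes if _gene_in_intron(query, g)]
    if y_hits:
        g = min(y_hits, key=lambda g: g.gene_id)
        return ClassCode("y", "", g.gene_id)

    return ClassCode("u")


@dataclass(frozen=True)
class GeneStatus:
    """Known / novel-intergenic / novel-intragenic status of an iso-seq gene."""

    status: str  # known | novel_intragenic | novel_intergenic
    codes: frozenset[str]

    @staticmethod
    def from_codes(codes: Iterable[str]) -> "GeneStatus":
        codes = frozenset(codes)
        if codes & KNOWN_CODES:
            return GeneStatus("known", codes)
        if "i" in codes:
            return GeneStatus("novel_intragenic", codes)
        return GeneStatus("novel_intergenic", codes)


def assign_gene_status(
    gene: GeneModel,
    codes_by_ref: dict[str, dict[str, ClassCode]],
) -> dict[str, GeneStatus]:
    """Per-reference gene status from the member transcripts' class codes.

    ``codes_by_ref`` maps reference label -> {transcript_id -> ClassCode}.
    """
    out = {}
    for ref_label, codes in codes_by_ref.items():
        member_codes = [
            codes[t.transcript_id].code
            for t in gene.transcripts
            if t.transcript_id in codes
        ]
        out[ref_label] = GeneStatus.from_codes(member_codes)
    return out


def combined_membership(statuses: dict[str, GeneStatus]) -> str:
    """Human-readable combined membership across references.

    E.g. ``known:refA,refB`` for genes known in both sets, or
    ``known:refB|novel_intergenic:refA`` for a refB-specific gene that is
    intergenic by refA — the categories of the cross-annotation membership
    comparison.
    """
    by_status: dict[str, list[str]] = {}
    for ref in sorted(statuses):
        by_status.setdefault(statuses[ref].status, []).append(ref)
    return "|".join(
        f"{status}:{','.join(refs)}" for status, refs in sorted(by_status.items())
    )


def detect_fused_transcripts(
    queries: Iterable[TranscriptModel],
    reference: AnnotationSet,
) -> dict[str, list[str]]:
    """Transcripts whose exons overlap >= 2 distinct same-strand reference genes.

    Returns {query transcript_id -> sorted overlapped reference gene ids}.
    """
    fused: dict[str, list[str]] = {}
    for q in queries:
        hit_genes: set[str] = set()
        for g in reference.overlapping_genes(
            q.chrom, q.start, q.end, strand=q.strand
        ):
            if any(
                qe.overlap_len(re_) > 0
                for t in g.transcripts
                for qe in q.exons
                for re_ in t.exons
            ):
                hit_genes.add(g.gene_id)
        if len(hit_genes) >= 2:
            fused[q.transcript_id] = sorted(hit_genes)
    return fused


def classify_catalogue(
    catalogue: AnnotationSet,
    references: dict[str, AnnotationSet],
    config: ClassifierConfig = ClassifierConfig(),
) -> dict[str, dict[str, ClassCode]]:
    """Classify every catalogue transcript against each reference.

    Returns {reference label -> {transcript_id -> ClassCode}}.
    """
    out: dict[str, dict[str, ClassCode]] = {}
    for label, ref in references.items():
        out[label] = {
            t.transcript_id: classify_transcript(t, ref, config)
            for t in catalogue.transcripts()
        }
    return out
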