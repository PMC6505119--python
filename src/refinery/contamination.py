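"""Genomic-DNA artifact filtering and cross-tissue catalogue merging.

Un-spliced long-read models whose downstream genomic context is A-rich are
likely internal-priming artifacts on genomic DNA: the oligo-dT primer can
anneal to a genomically encoded A-stretch rather than a true poly(A) tail.
Such models are flagged and removed.  Single-exon models seen by long reads
in only one tissue are also dropped, since they cannot be distinguished
from fragments of decayed transcripts.

The per-tissue catalogues are then merged: spliced models are unified when
their intron chains match junction-for-junction within a small positional
tolerance (5 nt by default), ignoring differences at the 5' terminus;
mono-exonic models are unified by reciprocal overlap.  The merged model
keeps the widest observed termini and the union of source tissues.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    chrom_length,
    cluster_genes,
    fetch_seq,
    revcomp,
)


@dataclass(frozen=True)
class PolyAFilterConfig:
    """Parameters of the genomic poly(A) internal-priming filter.

    run_length: minimum A-run length (nt) flagging a genomic A-stretch.
    max_mismatch: non-A bases tolerated inside the run.
    window: genomic window scanned immediately 3' of the model terminus.
    """

    run_length: int = 20
    max_mismatch: int = 1
    window: int = 30

    def __post_init__(self) -> None:
        if self.run_length > self.window:
            raise ValueError("run_length must be <= window")
        if self.max_mismatch >= self.run_length:
            raise ValueError("max_mismatch must be < run_length")


@dataclass(frozen=True)
class MergeConfig:
    """Parameters of the cross-tissue merge.

    junction_fuzz: positional tolerance (nt) when matching splice sites.
    ignore_5prime_difference: unify spliced models regardless of their
        5'-terminal exon end position.
    mono_min_reciprocal_overlap: fraction of the shorter model that two
        mono-exonic models must mutually overlap to be unified.
    """

    junction_fuzz: int = 5
    ignore_5prime_difference: bool = True
    mono_min_reciprocal_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.junction_fuzz < 0:
            raise ValueError("junction_fuzz must be >= 0")


def downstream_window(
    t: TranscriptModel, genome, window: int
) -> str:
    """Genomic sequence scanned by the poly(A) filter, on the transcript strand.

    For a '+' model this is the ``window`` nt immediately after its 3'
    terminal base; for a '-' model, the ``window`` nt immediately before its
    genomic start, reverse-complemented so that internal-priming A-stretches
    read as A on the transcript's own strand.  Truncated at chromosome ends.
    """
    if t.strand == "+":
        start = t.end
        end = min(t.end + window, chrom_length(genome, t.chrom))
        if start >= end:
            return ""
        return fetch_seq(genome, t.chrom, start, end)
    start = max(0, t.start - window)
    if start >= t.start:
        return ""
    return revcomp(fetch_seq(genome, t.chrom, start, t.start))


def has_a_run(seq: str, run_length: int, max_mismatch: int) -> bool:
    """True iff ``seq`` contains a substring of length >= run_length with
    at most ``max_mismatch`` non-A bases.

    Any qualifying longer substring contains a qualifying substring of
    exactly ``run_length``, so only windows of that length are scanned.
    """
    n = len(seq)
    if n < run_length:
        return False
    mismatches = sum(1 for c in seq[:run_length] if c != "A")
    if mismatches <= max_mismatch:
        return True
    for i in range(1, n - run_length + 1):
        mismatches += (seq[i + run_length - 1] != "A") - (seq[i - 1] != "A")
        if mismatches <= max_mismatch:
            return True
    return False


def flag_genomic_polyA(
    t: TranscriptModel, genome, config: PolyAFilterConfig = PolyAFilterConfig()
) -> bool:
    """True iff ``t`` looks like an internal-priming genomic-DNA artifact.

    Only un-spliced models are eligible: a spliced alignment demonstrates a
    real transcript regardless of downstream genomic A-content.
    """
    if t.is_spliced:
        return False
    window = downstream_window(t, genome, config.window)
    return has_a_run(window, config.run_length, config.max_mismatch)


def filter_genomic_polyA(
    transcripts: Iterable[TranscriptModel],
    genome,
    config: PolyAFilterConfig = PolyAFilterConfig(),
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition transcripts into (kept, flagged-as-genomic-artifact)."""
    kept, flagged = [], []
    for t in transcripts:
        (flagged if flag_genomic_polyA(t, genome, config) else kept).append(t)
    return kept, flagged


def drop_singleton_monoexons(
    transcripts: Iterable[TranscriptModel],
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition into (kept, dropped) removing single-exon single-tissue models.

    A model is dropped iff it has exactly one exon and long-read evidence
    (``source_tissues``) in exactly one tissue.  Spliced models and
    multi-tissue mono-exonic models are retained.
    """
    kept, dropped = [], []
    for t in transcripts:
        if t.n_exons == 1 and len(t.source_tissues) == 1:
            dropped.append(t)
        else:
            kept.append(t)
    return kept, dropped


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _chains_match(
    c1: Sequence[tuple[int, int]],
    c2: Sequence[tuple[int, int]],
    fuzz: int,
) -> bool:
    if len(c1) != len(c2):
        return False
    return all(
        abs(d1 - d2) <= fuzz and abs(a1 - a2) <= fuzz
        for (d1, a1), (d2, a2) in zip(c1, c2)
    )


def _merge_group(members: list[TranscriptModel]) -> TranscriptModel:
    """Collapse a group of matching models into one representative.

    The intron chain comes from the member with the longest span (ties:
    lexicographically smallest id); terminal exons are widened to the
    extreme observed termini; tissues are unioned; the id is the smallest
    member id so that re-merging is stable.
    """
    rep = min(members, key=lambda t: (-(t.end - t.start), t.transcript_id))
    start = min(t.start for t in members)
    end = max(t.end for t in members)
    tissues = frozenset().union(*(t.source_tissues for t in members))
    tid = min(t.transcript_id for t in members)
    exons = list(rep.exons)
    first = exons[0]
    exons[0] = GenomicInterval(first.chrom, min(start, first.start), first.end, first.strand)
    last = exons[-1]
    exons[-1] = GenomicInterval(last.chrom, last.start, max(end, last.end), last.strand)
    if len(exons) == 1:
        exons = [GenomicInterval(first.chrom, start, end, first.strand)]
    return TranscriptModel(
        transcript_id=tid,
        chrom=rep.chrom,
        strand=rep.strand,
        exons=tuple(exons),
        gene_id="",
        source_tissues=tissues,
    )


def merge_transcripts(
    transcripts: Sequence[TranscriptModel],
    config: MergeConfig = MergeConfig(),
) -> list[TranscriptModel]:
    """Unify matching models across tissues; deterministic under permutation."""
    transcripts = sorted(
        transcripts, key=lambda t: (t.chrom, t.strand, t.start, t.end, t.transcript_id)
    )
    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i, t in enumerate(transcripts):
        buckets[(t.chrom, t.strand, len(t.intron_chain))].append(i)

    uf = _UnionFind(len(transcripts))
    for (_, _, n_introns), idxs in buckets.items():
        for a_pos, i in enumerate(idxs):
            ti = transcripts[i]
            for j in idxs[a_pos + 1 :]:
                tj = transcripts[j]
                if n_introns == 0:
                    ov = ti.span.overlap_len(tj.span)
                    shorter = min(len(ti.span), len(tj.span))
                    if ov >= config.mono_min_reciprocal_overlap * shorter and ov > 0:
                        uf.union(i, j)
                else:
                    if ti.intron_chain[0][0] - tj.intron_chain[0][0] > config.junction_fuzz:
                        continue  # sorted by start; later j only drift further
                    if _chains_match(ti.intron_chain, tj.intron_chain, config.junction_fuzz):
                        if config.ignore_5prime_difference or _same_5prime_end(
                            ti, tj, config.junction_fuzz
                        ):
                            uf.union(i, j)

    groups: dict[int, list[TranscriptModel]] = defaultdict(list)
    for i, t in enumerate(transcripts):
        groups[uf.find(i)].append(t)
    merged = [_merge_group(members) for members in groups.values()]
    merged.sort(key=lambda t: (t.chrom, t.start, t.end, t.strand, t.transcript_id))
    return merged


def _same_5prime_end(t1: TranscriptModel, t2: TranscriptModel, fuzz: int) -> bool:
    return abs(t1.five_prime() - t2.five_prime()) <= fuzz


def merge_tissue_catalogues(
    per_tissue_sets: Sequence[AnnotationSet] | Sequence[Sequence[TranscriptModel]],
    config: MergeConfig = MergeConfig(),
    source_label: str = "isoseq",
) -> AnnotationSet:
    """Merge per-tissue transcript sets into one clustered catalogue."""
    pool: list[TranscriptModel] = []
    for s in per_tissue_sets:
        pool.extend(s.transcripts() if isinstance(s, AnnotationSet) else s)
    merged = merge_transcripts(pool, config)
    return cluster_genes(merged, source_label=source_label, gene_prefix="ISOG")
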