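"""Core genomic data model: intervals, transcripts, genes, annotation sets.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open ``[start, end)``.  GTF I/O
converts to/from the 1-based closed convention of that format; BED I/O is
already 0-based half-open.  Strand is ``"+"`` or ``"-"``; unstranded
transcripts are rejected at load because every downstream rule (splice-site
motifs, class codes, border extensions) is strand-dependent.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GtfError(ValueError):
    """Raised for malformed or unusable GTF input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction: the intron interval between two exons.

    ``donor`` is the 0-based position of the first intronic base and
    ``acceptor`` the position one past the last intronic base, i.e. the
    intron occupies ``[donor, acceptor)`` in genomic coordinates.  On the
    minus strand the biological donor site sits at the ``acceptor`` end;
    the coordinates here are purely genomic so that junctions from both
    strands can be compared positionally.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(f"junction donor {self.donor} >= acceptor {self.acceptor}")


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware exon chain on one chromosome.

    The atom of every comparison in the pipeline.  Exons are sorted,
    non-overlapping, half-open intervals on a single chromosome/strand.
    ``source_tissues`` records the tissues in which a long read produced
    this model (pre-rescue evidence).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    gene_id: str = ""
    source_tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r} (unstranded models are not supported)"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.chrom}, "
                    f"transcript on {self.chrom}"
                )
        for a, b in itertools.pairwise(exons):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if not isinstance(self.source_tissues, frozenset):
            object.__setattr__(self, "source_tissues", frozenset(self.source_tissues))

    # -- derived structure -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_spliced(self) -> bool:
        return len(self.exons) >= 2

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in itertools.pairwise(self.exons)
        )

    @property
    def junctions(self) -> tuple[Junction, ...]:
        return tuple(
            Junction(self.chrom, a.end, b.start, self.strand)
            for a, b in itertools.pairwise(self.exons)
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor, acceptor) genomic pairs; identity of spliced models."""
        return tuple((a.end, b.start) for a, b in itertools.pairwise(self.exons))

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def five_prime(self) -> int:
        """Genomic coordinate of the 5' terminus (strand-aware).

        On '+' this is ``start``; on '-' it is ``end`` (the half-open right
        edge, i.e. one past the 5'-most base).
        """
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    def with_(self, **kwargs) -> "TranscriptModel":
        return replace(self, **kwargs)


@dataclass
class GeneModel:
    """A cluster of transcripts sharing chromosome and strand."""

    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {self.gene_id}: members span multiple chrom/strand "
                f"({chroms}, {strands})"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )

    def tss(self) -> int:
        """Strand-aware 5'-most transcript start of the gene model."""
        return self.span.start if self.strand == "+" else self.span.end

    def tts(self) -> int:
        return self.span.end if self.strand == "+" else self.span.start

    def exonic_intervals(self) -> list[GenomicInterval]:
        """Union of member exons as merged, sorted intervals."""
        return merge_intervals(
            [e for t in self.transcripts for e in t.exons], self.chrom, self.strand
        )


def merge_intervals(
    intervals: Sequence[GenomicInterval], chrom: str, strand: str
) -> list[GenomicInterval]:
    """Merge overlapping/abutting intervals into a sorted disjoint list."""
    if not intervals:
        return []
    out: list[list[int]] = []
    for iv in sorted(intervals, key=lambda e: (e.start, e.end)):
        if out and iv.start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], iv.end)
        else:
            out.append([iv.start, iv.end])
    return [GenomicInterval(chrom, s, e, strand) for s, e in out]


class AnnotationSet:
    """An indexed collection of gene models from one source.

    Supports overlap queries over gene spans via per-(chrom, strand)
    interval trees.  Transcript ids are unique within a set.
    """

    def __init__(self, source: str, genes: Iterable[GeneModel]):
        self.source = source
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.chrom, g.span.start, g.span.end, g.gene_id)
        )
        self._by_tid: dict[str, TranscriptModel] = {}
        self._gene_of: dict[str, GeneModel] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for g in self.genes:
            for t in g.transcripts:
                if t.transcript_id in self._by_tid:
                    raise ValueError(
                        f"duplicate transcript_id {t.transcript_id!r} in set "
                        f"{source!r}"
                    )
                self._by_tid[t.transcript_id] = t
                self._gene_of[t.transcript_id] = g
            sp = g.span
            self._trees[(g.chrom, g.strand)].addi(sp.start, sp.end, g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self._by_tid)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes:
            yield from sorted(g.transcripts, key=lambda t: t.transcript_id)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._by_tid[transcript_id]

    def gene_of(self, transcript_id: str) -> GeneModel:
        return self._gene_of[transcript_id]

    def overlapping_genes(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneModel]:
        """Genes whose span overlaps [start, end); both strands if strand is None."""
        strands = STRANDS if strand is None else (strand,)
        hits = [
            iv.data
            for s in strands
            for iv in self._trees.get((chrom, s), IntervalTree()).overlap(start, end)
        ]
        return sorted(hits, key=lambda g: (g.span.start, g.span.end, g.gene_id))


# ---------------------------------------------------------------------------
# GTF I/O


def _parse_gtf_line(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GtfError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
    try:
        start, end = int(fields[3]), int(fields[4])
    except ValueError:
        raise GtfError(f"line {lineno}: non-integer coordinates {fields[3]!r}/{fields[4]!r}")
    if start < 1 or end < start:
        raise GtfError(f"line {lineno}: invalid 1-based coordinates {start}-{end}")
    return feature_from_line(line, dialect=None)


def read_gtf(path, source_label: str = "") -> AnnotationSet:
    """Read a GTF file into an :class:`AnnotationSet`.

    Only ``exon`` features are structural; they must carry ``transcript_id``
    and may carry ``gene_id``.  1-based closed GTF coordinates are converted
    to the internal 0-based half-open convention.  Transcripts with a
    ``gene_id`` are grouped by it; transcripts without one become singleton
    provisional genes (use :func:`cluster_genes` to assign genes).
    """
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    strands: dict[str, str] = {}
    gene_ids: dict[str, str] = {}
    tissue_of: dict[str, frozenset[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = _parse_gtf_line(line, lineno)
            if feat.featuretype != "exon":
                continue
            if "transcript_id" not in feat.attributes:
                raise GtfError(f"line {lineno}: exon feature without transcript_id")
            tid = feat.attributes["transcript_id"][0]
            if feat.strand not in STRANDS:
                raise GtfError(
                    f"line {lineno}: transcript {tid!r} is unstranded "
                    f"(strand {feat.strand!r}); stranded models are required"
                )
            if tid in strands and strands[tid] != feat.strand:
                raise GtfError(f"line {lineno}: conflicting strand for {tid!r}")
            if tid not in exons:
                order.append(tid)
            strands[tid] = feat.strand
            exons[tid].append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
            if "gene_id" in feat.attributes and feat.attributes["gene_id"][0]:
                gene_ids.setdefault(tid, feat.attributes["gene_id"][0])
            if "source_tissues" in feat.attributes:
                tissue_of[tid] = frozenset(
                    feat.attributes["source_tissues"][0].split(",")
                ) - {""}

    transcripts = []
    for tid in order:
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                chrom=exons[tid][0].chrom,
                strand=strands[tid],
                exons=tuple(exons[tid]),
                gene_id=gene_ids.get(tid, ""),
                source_tissues=tissue_of.get(tid, frozenset()),
            )
        )
    return group_by_gene_id(transcripts, source_label)


def group_by_gene_id(
    transcripts: Sequence[TranscriptModel], source_label: str = ""
) -> AnnotationSet:
    """Group transcripts into genes by their gene_id (singletons if absent)."""
    groups: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        gid = t.gene_id or t.transcript_id
        groups[gid].append(t.with_(gene_id=gid))
    genes = [GeneModel(gid, ts) for gid, ts in groups.items()]
    return AnnotationSet(source_label, genes)


def write_gtf(annotation: AnnotationSet, path) -> None:
    """Write an annotation set as GTF (transcript + exon features)."""
    with open(path, "w") as fh:
        for gene in annotation.genes:
            for t in sorted(gene.transcripts, key=lambda t: (t.start, t.transcript_id)):
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                if t.source_tissues:
                    tissues = ",".join(sorted(t.source_tissues))
                    attrs += f' source_tissues "{tissues}";'
                fh.write(
                    f"{t.chrom}\t{annotation.source or 'refinery'}\ttranscript\t"
                    f"{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{t.chrom}\t{annotation.source or 'refinery'}\texon\t"
                        f"{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Gene clustering


def cluster_genes(
    transcripts: Sequence[TranscriptModel],
    source_label: str = "",
    gene_prefix: str = "G",
) -> AnnotationSet:
    """Cluster transcripts into genes by >= 1 nt span overlap, strand-aware.

    Transcripts on the same chromosome and strand whose spans overlap by at
    least one nucleotide (transitively closed) share one gene.  Gene ids are
    deterministic: numbered by (chrom, leftmost coordinate) of the cluster.
    Abutting half-open spans (end == start) do not overlap.
    """
    buckets: dict[tuple[str, str], list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        buckets[(t.chrom, t.strand)].append(t)

    clusters: list[tuple[str, int, list[TranscriptModel]]] = []
    for (chrom, _strand), members in buckets.items():
        members = sorted(members, key=lambda t: (t.start, t.end, t.transcript_id))
        current: list[TranscriptModel] = []
        cur_end = -1
        for t in members:
            if current and t.start < cur_end:
                current.append(t)
                cur_end = max(cur_end, t.end)
            else:
                if current:
                    clusters.append((chrom, current[0].start, current))
                current = [t]
                cur_end = t.end
        if current:
            clusters.append((chrom, current[0].start, current))

    clusters.sort(key=lambda c: (c[0], c[1], c[2][0].strand, c[2][0].transcript_id))
    genes = []
    width = max(4, len(str(len(clusters))))
    for i, (_chrom, _start, members) in enumerate(clusters, start=1):
        gid = f"{gene_prefix}{i:0{width}d}"
        genes.append(GeneModel(gid, [t.with_(gene_id=gid) for t in members]))
    return AnnotationSet(source_label, genes)


# ---------------------------------------------------------------------------
# Genome sequence access and splice-site inspection


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome sequence ``[start, end)`` as an uppercase string.

    Accepts a ``pyfaidx.Fasta``-like object (``genome[chrom][start:end]``)
    or a plain mapping of chromosome name to sequence string.
    """
    if start < 0 or end < start:
        raise ValueError(f"invalid fetch range {chrom}:{start}-{end}")
    record = genome[chrom]
    if isinstance(record, str):
        if end > len(record):
            raise ValueError(
                f"fetch {chrom}:{start}-{end} beyond chromosome length {len(record)}"
            )
        return record[start:end].upper()
    if end > len(record):
        raise ValueError(
            f"fetch {chrom}:{start}-{end} beyond chromosome length {len(record)}"
        )
    piece = record[start:end]
    return str(getattr(piece, "seq", piece)).upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


@dataclass
class SpliceSiteReport:
    """Per-motif counts of (donor, acceptor) dinucleotides and canonical fraction."""

    motif_counts: dict[tuple[str, str], int]
    n_introns: int
    n_canonical: int

    @property
    def fraction_canonical(self) -> float | None:
        if self.n_introns == 0:
            return None
        return self.n_canonical / self.n_introns


CANONICAL_DONORS = ("GT", "GC")
CANONICAL_ACCEPTOR = "AG"


def splice_motifs(t: TranscriptModel, genome) -> list[tuple[str, str]]:
    """Strand-aware (donor, acceptor) dinucleotides for each intron of ``t``."""
    out = []
    for iv in t.introns:
        left = fetch_seq(genome, t.chrom, iv.start, iv.start + 2)
        right = fetch_seq(genome, t.chrom, iv.end - 2, iv.end)
        if t.strand == "+":
            out.append((left, right))
        else:
            out.append((revcomp(right), revcomp(left)))
    return out


def canonical_splice_fraction(annotation: AnnotationSet, genome) -> SpliceSiteReport:
    """Canonical splice-site fraction over the unique introns of a set.

    An intron is canonical iff its strand-aware donor dinucleotide is GT or
    GC and its acceptor is AG.  Each distinct (chrom, donor, acceptor,
    strand) intron is counted once.
    """
    seen: set[Junction] = set()
    counts: dict[tuple[str, str], int] = defaultdict(int)
    n_canonical = 0
    for t in sorted(annotation.transcripts(), key=lambda t: t.transcript_id):
        motifs = splice_motifs(t, genome)
        for j, motif in zip(t.junctions, motifs):
            if j in seen:
                continue
            seen.add(j)
            counts[motif] += 1
            if motif[0] in CANONICAL_DONORS and motif[1] == CANONICAL_ACCEPTOR:
                n_canonical += 1
    return SpliceSiteReport(dict(counts), len(seen), n_canonical)
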