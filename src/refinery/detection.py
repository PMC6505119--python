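"""Transcript x tissue detection: long-read presence plus short-read rescue.

Relying on long reads alone over-predicts tissue specificity, because a
transcript absent from one tissue's long-read data may simply be under-
sampled there.  A transcript is therefore marked *detected* in a tissue if

1. a long read produced it in that tissue (``detected_longread``), or
2. it was produced by long reads elsewhere, every one of its splice
   junctions has spanning short-read support in the tissue of interest,
   and its expression there exceeds the FPKM threshold
   (``detected_rescued``).

The default FPKM threshold is 0.1 — the inflection point of the expression
distribution of transcripts seen by long reads in more than one tissue —
and the comparison is strict (> threshold).  Mono-exonic transcripts have
no junctions to validate, so they can only be rescued on expression alone.
"""

from __future__ import annotations

import enum
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, Junction, TranscriptModel

DEFAULT_FPKM_THRESHOLD = 0.1


class Detection(enum.Enum):
    UNDETECTED = "undetected"
    LONGREAD = "detected_longread"
    RESCUED = "detected_rescued"

    def __bool__(self) -> bool:
        return self is not Detection.UNDETECTED


class JunctionSupportTable:
    """Spanning-read counts per (tissue, junction)."""

    def __init__(self, counts: Mapping[tuple[str, Junction], int] | None = None):
        self._counts: dict[tuple[str, Junction], int] = {}
        if counts:
            for key, c in counts.items():
                self.add(key[0], key[1], c)

    def add(self, tissue: str, junction: Junction, count: int) -> None:
        if count < 0:
            raise ValueError("junction read count must be >= 0")
        key = (tissue, junction)
        self._counts[key] = self._counts.get(key, 0) + count

    def count(self, tissue: str, junction: Junction) -> int:
        return self._counts.get((tissue, junction), 0)

    def __len__(self) -> int:
        return len(self._counts)

    @staticmethod
    def from_tsv(path) -> "JunctionSupportTable":
        """Load from TSV with columns tissue, chrom, donor, acceptor, strand, count."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        table = JunctionSupportTable()
        for row in df.itertuples(index=False):
            table.add(
                row.tissue,
                Junction(row.chrom, int(row.donor), int(row.acceptor), row.strand),
                int(row.count),
            )
        return table

    def to_tsv(self, path) -> None:
        rows = [
            (tissue, j.chrom, j.donor, j.acceptor, j.strand, c)
            for (tissue, j), c in sorted(
                self._counts.items(),
                key=lambda kv: (kv[0][0], kv[0][1].chrom, kv[0][1].donor, kv[0][1].acceptor, kv[0][1].strand),
            )
        ]
        pd.DataFrame(
            rows, columns=["tissue", "chrom", "donor", "acceptor", "strand", "count"]
        ).to_csv(path, sep="\t", index=False)


class ExpressionTable:
    """FPKM per (transcript_id, tissue); missing entries are 0."""

    def __init__(self, fpkm: Mapping[tuple[str, str], float] | None = None):
        self._fpkm: dict[tuple[str, str], float] = {}
        if fpkm:
            for (tid, tissue), v in fpkm.items():
                self.set(tid, tissue, v)

    def set(self, transcript_id: str, tissue: str, fpkm: float) -> None:
        if fpkm < 0:
            raise ValueError("FPKM must be non-negative")
        self._fpkm[(transcript_id, tissue)] = float(fpkm)

    def fpkm(self, transcript_id: str, tissue: str) -> float:
        return self._fpkm.get((transcript_id, tissue), 0.0)

    def values(self) -> list[float]:
        return list(self._fpkm.values())

    @staticmethod
    def from_tsv(path) -> "ExpressionTable":
        """Load a transcript x tissue FPKM matrix (first column transcript_id)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        table = ExpressionTable()
        for tid, row in df.iterrows():
            for tissue, v in row.items():
                if v > 0:
                    table.set(str(tid), str(tissue), float(v))
        return table

    def to_tsv(self, path, transcript_ids: Sequence[str], tissues: Sequence[str]) -> None:
        data = {
            tissue: [self.fpkm(tid, tissue) for tid in transcript_ids]
            for tissue in tissues
        }
        df = pd.DataFrame(data, index=pd.Index(transcript_ids, name="transcript_id"))
        df.to_csv(path, sep="\t", float_format="%.6g")


def estimate_inflection_threshold(
    fpkm_values: Sequence[float],
    default: float = DEFAULT_FPKM_THRESHOLD,
) -> float:
    """Knee of the empirical log10-FPKM cumulative curve.

    Sorts the log10 values, draws the chord from the first to the last
    point of the cumulative curve and returns the FPKM at the point of
    maximum perpendicular distance below the chord (kneedle-style).  With
    fewer than 10 positive values, or a degenerate (constant) sample, the
    fixed default is returned instead.
    """
    vals = np.asarray([v for v in fpkm_values if v > 0], dtype=float)
    if vals.size < 10:
        warnings.warn(
            f"only {vals.size} positive FPKM values; falling back to default "
            f"threshold {default}",
            stacklevel=2,
        )
        return default
    x = np.sort(np.log10(vals))
    if x[0] == x[-1]:
        return default
    y = np.arange(1, x.size + 1) / x.size
    # chord from (x0, y0) to (xn, yn); signed perpendicular distance
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    dist = ((x - x0) * dy - (y - y0) * dx) / norm
    knee = int(np.argmax(dist))
    return float(10 ** x[knee])


def is_detected(
    transcript: TranscriptModel,
    tissue: str,
    junction_support: JunctionSupportTable,
    expression: ExpressionTable,
    threshold: float = DEFAULT_FPKM_THRESHOLD,
    min_junction_reads: int = 1,
    known_tissues: Iterable[str] | None = None,
) -> Detection:
    """Detection status of one transcript in one tissue (see module docs)."""
    if known_tissues is not None and tissue not in set(known_tissues):
        raise ValueError(f"unknown tissue {tissue!r}")
    if tissue in transcript.source_tissues:
        return Detection.LONGREAD
    if not transcript.source_tissues:
        return Detection.UNDETECTED
    for j in transcript.junctions:
        if junction_support.count(tissue, j) < min_junction_reads:
            return Detection.UNDETECTED
    if expression.fpkm(transcript.transcript_id, tissue) > threshold:
        return Detection.RESCUED
    return Detection.UNDETECTED


@dataclass
class DetectionMatrix:
    """Detection status per (transcript_id, tissue)."""

    tissues: tuple[str, ...]
    status: dict[tuple[str, str], Detection] = field(default_factory=dict)

    def get(self, transcript_id: str, tissue: str) -> Detection:
        return self.status.get((transcript_id, tissue), Detection.UNDETECTED)

    def detected_tissues(self, transcript_id: str) -> list[str]:
        return [t for t in self.tissues if self.get(transcript_id, t)]

    def detected_transcripts(self, tissue: str) -> list[str]:
        return sorted(
            {tid for (tid, ts), st in self.status.items() if ts == tissue and st}
        )

    def is_tissue_specific(self, transcript_id: str) -> str | None:
        """The single tissue a transcript is detected in, or None."""
        hits = self.detected_tissues(transcript_id)
        return hits[0] if len(hits) == 1 else None

    def to_frame(self) -> pd.DataFrame:
        tids = sorted({tid for tid, _ in self.status})
        return pd.DataFrame(
            {
                tissue: [self.get(tid, tissue).value for tid in tids]
                for tissue in self.tissues
            },
            index=pd.Index(tids, name="transcript_id"),
        )


def build_detection_matrix(
    catalogue: AnnotationSet,
    tissues: Sequence[str],
    junction_support: JunctionSupportTable,
    expression: ExpressionTable,
    threshold: float = DEFAULT_FPKM_THRESHOLD,
    min_junction_reads: int = 1,
) -> DetectionMatrix:
    matrix = DetectionMatrix(tuple(tissues))
    for t in catalogue.transcripts():
        for tissue in tissues:
            st = is_detected(
                t, tissue, junction_support, expression, threshold, min_junction_reads
            )
            if st:
                matrix.status[(t.transcript_id, tissue)] = st
    return matrix


@dataclass
class TissueSummary:
    """Per-tissue detection summary plus tissue-specific transcript/gene lists."""

    table: pd.DataFrame
    tissue_specific_transcripts: dict[str, list[str]]
    tissue_specific_genes: dict[str, list[str]]


def summarize_tissues(
    matrix: DetectionMatrix, catalogue: AnnotationSet
) -> TissueSummary:
    """Per-tissue gene/transcript counts in the layout of the study's
    distribution-across-tissues table, plus tissue-specific calls.

    A transcript is tissue-specific when detected (by either route) in
    exactly one tissue; a gene is tissue-specific when all of its detected
    member transcripts are specific to the same single tissue.
    """
    rows = []
    ts_transcripts: dict[str, list[str]] = {t: [] for t in matrix.tissues}
    ts_genes: dict[str, list[str]] = {t: [] for t in matrix.tissues}

    for tid in sorted(t.transcript_id for t in catalogue.transcripts()):
        spec = matrix.is_tissue_specific(tid)
        if spec is not None:
            ts_transcripts[spec].append(tid)

    for gene in catalogue.genes:
        tissues_hit = {
            ts
            for t in gene.transcripts
            for ts in matrix.detected_tissues(t.transcript_id)
        }
        if len(tissues_hit) == 1:
            ts_genes[next(iter(tissues_hit))].append(gene.gene_id)

    for tissue in matrix.tissues:
        detected = matrix.detected_transcripts(tissue)
        genes = defaultdict(list)
        for tid in detected:
            genes[catalogue.gene_of(tid).gene_id].append(tid)
        n_tr = len(detected)
        n_genes = len(genes)
        multi = sum(len(v) for v in genes.values() if len(v) > 1)
        single = sum(len(v) for v in genes.values() if len(v) == 1)
        mean_exons = (
            float(np.mean([catalogue.transcript(tid).n_exons for tid in detected]))
            if detected
            else 0.0
        )
        rows.append(
            {
                "tissue": tissue,
                "n_detected_genes": n_genes,
                "n_detected_transcripts": n_tr,
                "transcripts_per_gene": (n_tr / n_genes) if n_genes else 0.0,
                "mean_exons_per_transcript": mean_exons,
                "n_from_multi_transcript_genes": multi,
                "n_from_single_transcript_genes": single,
                "n_tissue_specific_transcripts": len(ts_transcripts[tissue]),
                "n_tissue_specific_genes": len(ts_genes[tissue]),
            }
        )
    return TissueSummary(
        pd.DataFrame(rows).set_index("tissue"), ts_transcripts, ts_genes
    )
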