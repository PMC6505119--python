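"""Synthetic input bundles with machine-readable planted truth.

Generates, from a seed and a configuration, a desk-scale genome, two
reference annotations, per-tissue long-read transcript sets, junction
support and FPKM tables, ChIP peaks, 3'-RNA-seq reads and CAGE tags — with
every planted feature recorded in a truth table so each pipeline stage can
be tested end-to-end without any external download.

Planted feature families
------------------------
* one reference gene per structural class role (=, j, c, k, o, s, x, i, y,
  u and fused transcripts), each in its own genomic slot;
* transcripts with controlled spliced sequence planting premature stop
  codons at configured distances from the final junction (NMD boundary),
  ORF-free long transcripts (lncRNA) and a short non-coding control;
* un-spliced genomic-DNA artifacts with an A-rich downstream window, plus
  sub-threshold window controls and single-tissue mono-exon models that
  the singleton filter must remove;
* cross-tissue rescue cases (full junction support + FPKM above threshold
  in a tissue without long-read evidence) and near-miss controls;
* one gene per alternative-splicing event type, built so that exactly one
  event of that type (and nothing else) distinguishes its two transcripts;
* 5'/3' gene-border extensions with matched ChIP peaks, contained or
  boundary-straddling 3' reads and CAGE tags placed to yield each verdict.

Spliced planted introns carry canonical GT..AG motifs (reference genes take
priority where strands conflict); a configurable fraction of long-read-only
introns is deliberately made non-canonical.  All randomness flows through
streams keyed by (seed, feature family), so adding a family does not
perturb earlier draws and the same seed yields a byte-identical bundle.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationSet,
    GenomicInterval,
    GeneModel,
    TranscriptModel,
    group_by_gene_id,
    revcomp,
    write_gtf,
)
from .borders import BedRead, Peak, PeakSet
from .detection import ExpressionTable, JunctionSupportTable

_STREAMS = {
    "genome": 1,
    "layout": 2,
    "tissues": 3,
    "expression": 4,
    "junctions": 5,
    "noncanonical": 6,
    "dropout": 7,
    "reads": 8,
}


@dataclass
class SimulationConfig:
    """Scale, planted-feature counts and noise rates of a synthetic bundle.

    Defaults are the desk-scale study conditions: a 2 x 500 kb genome,
    three tissues, ~70 reference genes and a handful of planted features
    per structural class — small enough for seconds-scale runs while
    exercising every pipeline rule including its boundary cases.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    slot_pitch: int = 10_000
    tissues: tuple[str, ...] = ("brain", "liver", "spleen")

    # structural-class roles (one dedicated reference gene each)
    n_exact: int = 10
    n_j: int = 5
    n_c: int = 4
    n_k: int = 4
    n_o: int = 3
    n_s: int = 3
    n_x: int = 3
    n_i: int = 3
    n_y: int = 2
    n_u: int = 3
    n_fused: int = 2
    n_refb_dropped: int = 2  # exact-role genes absent from the second reference
    n_refb_only: int = 2  # reference genes present only in the second reference

    # biotype roles; NMD offsets are distances (nt) from the last stop base
    # to the final junction — only offsets > 50 are NMD
    nmd_offsets: tuple[int, ...] = (49, 50, 51, 120)
    n_coding: int = 2
    n_lncrna: int = 3
    n_short_noncoding: int = 1

    # contamination roles
    n_gdna: int = 4
    n_polya_controls: int = 2
    n_singleton_monoexons: int = 2

    # detection roles
    n_rescue: int = 4
    n_rescue_junction_controls: int = 2
    n_rescue_fpkm_controls: int = 1
    rescue_fpkm: float = 0.8
    rescue_control_fpkm: float = 0.05
    fpkm_low: float = 0.3
    fpkm_high: float = 30.0
    junction_reads_low: int = 5
    junction_reads_high: int = 50

    # border-extension roles
    ext5_lengths: tuple[int, ...] = (90, 120, 150, 210)
    ext3_lengths: tuple[int, ...] = (200, 300, 400, 500)
    ext_both_lengths: tuple[tuple[int, int], ...] = ((120, 300), (180, 420))
    three_prime_read_length: int = 40
    n_gain_shared_reads: int = 10
    n_gain_extension_reads: int = 4

    # noise rates (defaults are the noiseless study conditions except the
    # deliberate non-canonical splice-motif fraction)
    junction_dropout: float = 0.0
    non_canonical_fraction: float = 0.03

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.tissues) < 3:
            raise ValueError("at least 3 tissues are required for the planted roles")


TRUTH_COLUMNS = [
    "object_id",
    "kind",
    "role",
    "chrom",
    "strand",
    "class_a",
    "class_b",
    "status_a",
    "status_b",
    "biotype",
    "removed_by",
    "detection",
    "ref_gene_id",
    "ext5",
    "ext3",
    "chip_promoter",
    "chip_body",
    "three_prime_validated",
    "cage_verdict",
    "event_type",
    "n_events",
    "n_ir_events",
    "partner_gene_ids",
    "value",
]


class TruthTable:
    """Planted ground truth, one row per planted object (kind-discriminated)."""

    def __init__(self, rows: list[dict] | None = None):
        self.rows: list[dict] = rows or []

    def add(self, **kwargs) -> None:
        row = {c: kwargs.get(c) for c in TRUTH_COLUMNS}
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=TRUTH_COLUMNS)

    def transcripts(self) -> pd.DataFrame:
        df = self.frame()
        return df[df["kind"] == "transcript"]

    def of_role(self, role: str) -> pd.DataFrame:
        df = self.frame()
        return df[df["role"] == role]

    def to_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype={"object_id": str})
        return TruthTable(df.to_dict("records"))


@dataclass
class SimBundle:
    """In-memory synthetic bundle plus writers for the on-disk layout."""

    config: SimulationConfig
    genome: dict[str, str]
    references: dict[str, AnnotationSet]
    transcripts: list[TranscriptModel]
    tissue_variants: dict[tuple[str, str], tuple[GenomicInterval, ...]]
    junction_support: JunctionSupportTable
    expression: ExpressionTable
    peaks: PeakSet
    three_prime_reads: list[BedRead]
    cage_tags: list[BedRead]
    truth: TruthTable

    def per_tissue_transcripts(self, tissue: str) -> list[TranscriptModel]:
        """The long-read models observed in one tissue (variant termini applied)."""
        out = []
        for t in self.transcripts:
            if tissue not in t.source_tissues:
                continue
            exons = self.tissue_variants.get((t.transcript_id, tissue), t.exons)
            out.append(
                TranscriptModel(
                    t.transcript_id, t.chrom, t.strand, exons, "", frozenset({tissue})
                )
            )
        return sorted(out, key=lambda t: (t.chrom, t.start, t.transcript_id))

    def write(self, out_dir) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths: dict[str, str] = {}

        fa = os.path.join(out_dir, "genome.fa")
        with open(fa, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        paths["genome"] = fa

        for label, ref in sorted(self.references.items()):
            p = os.path.join(out_dir, f"ref_{label}.gtf")
            write_gtf(ref, p)
            paths[f"ref_{label}"] = p

        for tissue in self.config.tissues:
            p = os.path.join(out_dir, f"isoseq_{tissue}.gtf")
            write_gtf(
                group_by_gene_id(self.per_tissue_transcripts(tissue), f"isoseq_{tissue}"),
                p,
            )
            paths[f"isoseq_{tissue}"] = p

        p = os.path.join(out_dir, "junctions.tsv")
        self.junction_support.to_tsv(p)
        paths["junctions"] = p

        p = os.path.join(out_dir, "fpkm.tsv")
        tids = sorted({t.transcript_id for t in self.transcripts})
        self.expression.to_tsv(p, tids, list(self.config.tissues))
        paths["fpkm"] = p

        p = os.path.join(out_dir, "peaks.bed")
        with open(p, "w") as fh:
            for pk in sorted(
                self.peaks.peaks,
                key=lambda k: (k.interval.chrom, k.interval.start, k.mark, k.sample),
            ):
                iv = pk.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.mark}\t{pk.sample}\t"
                    f"{1 if pk.significant else 0}\n"
                )
        paths["peaks"] = p

        for name, reads in (
            ("three_prime_reads.bed", self.three_prime_reads),
            ("cage_tags.bed", self.cage_tags),
        ):
            p = os.path.join(out_dir, name)
            with open(p, "w") as fh:
                for r in sorted(
                    reads, key=lambda r: (r.interval.chrom, r.interval.start, r.name)
                ):
                    iv = r.interval
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\t"
                        f"{1 if r.unique else 0}\t{iv.strand}\n"
                    )
            paths[name.split(".")[0]] = p

        p = os.path.join(out_dir, "truth.tsv")
        self.truth.to_tsv(p)
        paths["truth"] = p
        return paths


# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
        rng = self._rng("genome")
        self.arrays = {
            c: rng.choice(np.array(list("ACGT")), size=config.chrom_length)
            for c in self.chroms
        }
        n_slots = (config.chrom_length // config.slot_pitch) - 1
        self.slots = [
            (c, base * config.slot_pitch)
            for c in self.chroms
            for base in range(n_slots)
        ]
        self.slot_idx = 0
        self.ref_a: list[TranscriptModel] = []
        self.ref_b: list[TranscriptModel] = []
        self.transcripts: list[TranscriptModel] = []
        self.tissue_variants: dict[tuple[str, str], tuple[GenomicInterval, ...]] = {}
        self.junctions = JunctionSupportTable()
        self.expression = ExpressionTable()
        self.peaks: list[Peak] = []
        self.three_prime: list[BedRead] = []
        self.cage: list[BedRead] = []
        self.truth = TruthTable()
        self._tid = 0
        self._gid = 0
        self._read_id = 0
        self._tissue_rng = self._rng("tissues")
        self._expr_rng = self._rng("expression")
        self._junc_rng = self._rng("junctions")
        self._extra_support: list[tuple[str, TranscriptModel, int | None]] = []

    def _rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.cfg.seed % (2**31), _STREAMS[stream]])

    # -- identifiers and slots --------------------------------------------

    def next_slot(self) -> tuple[str, int, str]:
        if self.slot_idx >= len(self.slots):
            raise ValueError(
                "infeasible placement: planted feature counts exceed the "
                "available genomic slots; increase chrom_length or n_chroms"
            )
        chrom, base = self.slots[self.slot_idx]
        strand = "+" if self.slot_idx % 2 == 0 else "-"
        self.slot_idx += 1
        return chrom, base, strand

    def new_tid(self) -> str:
        self._tid += 1
        return f"PB.{self._tid:04d}"

    def new_ref_gid(self) -> str:
        self._gid += 1
        return f"RG{self._gid:03d}"

    def new_read_name(self) -> str:
        self._read_id += 1
        return f"read{self._read_id:05d}"

    # -- sequence planting --------------------------------------------------

    def write_seq(self, chrom: str, start: int, seq: str) -> None:
        self.arrays[chrom][start : start + len(seq)] = list(seq)

    def write_spliced_sequence(self, t: TranscriptModel, seq: str) -> None:
        """Plant ``seq`` as the spliced (5'->3') sequence of ``t``."""
        if len(seq) != t.spliced_length:
            raise ValueError("sequence length must equal spliced length")
        genomic = revcomp(seq) if t.strand == "-" else seq
        pos = 0
        for e in t.exons:
            self.write_seq(t.chrom, e.start, genomic[pos : pos + len(e)])
            pos += len(e)

    # -- transcript helpers --------------------------------------------------

    @staticmethod
    def _exons(chrom: str, strand: str, pairs: Sequence[tuple[int, int]]):
        return tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs)

    def ref_gene(
        self,
        chrom: str,
        base: int,
        strand: str,
        pairs: Sequence[tuple[int, int]],
        in_a: bool = True,
        in_b: bool = True,
    ) -> str:
        gid = self.new_ref_gid()
        t = TranscriptModel(
            f"{gid}.t1", chrom, strand, self._exons(chrom, strand, pairs), gid
        )
        if in_a:
            self.ref_a.append(t)
        if in_b:
            self.ref_b.append(t)
        return gid

    def pick_tissues(self, n: int) -> frozenset[str]:
        idx = sorted(
            self._tissue_rng.choice(len(self.cfg.tissues), size=n, replace=False)
        )
        return frozenset(self.cfg.tissues[i] for i in idx)

    def iso(
        self,
        chrom: str,
        strand: str,
        pairs: Sequence[tuple[int, int]],
        tissues: frozenset[str],
        fpkm: dict[str, float] | None = None,
    ) -> TranscriptModel:
        """Register a long-read model with expression and junction support
        in its source tissues."""
        t = TranscriptModel(
            self.new_tid(), chrom, strand, self._exons(chrom, strand, pairs),
            "", tissues,
        )
        self.transcripts.append(t)
        for tissue in sorted(tissues):
            v = fpkm.get(tissue) if fpkm else None
            if v is None:
                lo, hi = np.log(self.cfg.fpkm_low), np.log(self.cfg.fpkm_high)
                v = float(np.exp(self._expr_rng.uniform(lo, hi)))
            self.expression.set(t.transcript_id, tissue, v)
            self._extra_support.append((tissue, t, None))
        return t

    def support_junctions(
        self, tissue: str, t: TranscriptModel, skip_index: int | None = None
    ) -> None:
        self._extra_support.append((tissue, t, -1 if skip_index is None else skip_index))

    def _flush_support(self) -> None:
        """Materialise junction-support counts in registration order."""
        for tissue, t, skip in self._extra_support:
            for i, j in enumerate(t.junctions):
                if skip is not None and skip >= 0 and i == skip:
                    continue
                count = int(
                    self._junc_rng.integers(
                        self.cfg.junction_reads_low, self.cfg.junction_reads_high + 1
                    )
                )
                self.junctions.add(tissue, j, count)

    # -- standard layouts ---------------------------------------------------

    @staticmethod
    def std_pairs(base: int, n_exons: int = 4, exon_len: int = 200, pitch: int = 700):
        start = base + 1000
        return [
            (start + i * pitch, start + i * pitch + exon_len) for i in range(n_exons)
        ]

    # -----------------------------------------------------------------------
    # roles

    def plant_exact(self) -> None:
        for i in range(self.cfg.n_exact):
            chrom, base, strand = self.next_slot()
            in_b = i >= self.cfg.n_refb_dropped
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs, in_a=True, in_b=in_b)
            if i < 3:
                tissues = self.pick_tissues(2)
            else:
                tissues = self.pick_tissues(1 + (i % 2))
            t = self.iso(chrom, strand, pairs, tissues)
            if i < 3 and len(tissues) == 2:
                # one tissue observed a 5'-truncated variant (and, for one
                # gene, a 5-bp-jittered first donor) that the merge must
                # collapse back onto the full model
                variant_tissue = sorted(tissues)[1]
                vp = [list(p) for p in pairs]
                if strand == "+":
                    vp[0][0] += 150
                    if i == 1:
                        vp[0][1] += 3
                else:
                    vp[-1][1] -= 150
                    if i == 1:
                        vp[-1][0] -= 3
                self.tissue_variants[(t.transcript_id, variant_tissue)] = self._exons(
                    chrom, strand, [tuple(p) for p in vp]
                )
            class_b = "=" if in_b else "u"
            status_b = "known" if in_b else "novel_intergenic"
            self._truth_transcript(
                t, "exact", class_a="=", class_b=class_b,
                status_a="known", status_b=status_b, ref_gene_id=gid,
            )

    def plant_refb_only(self) -> None:
        for _ in range(self.cfg.n_refb_only):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs, in_a=False, in_b=True)
            t = self.iso(chrom, strand, pairs, self.pick_tissues(2))
            self._truth_transcript(
                t, "refb_only", class_a="u", class_b="=",
                status_a="novel_intergenic", status_b="known", ref_gene_id=gid,
            )

    def plant_structural(self) -> None:
        for _ in range(self.cfg.n_j):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            t = self.iso(chrom, strand, [pairs[0], pairs[2], pairs[3]], self.pick_tissues(2))
            self._truth_transcript(t, "class_j", class_a="j", class_b="j",
                                   status_a="known", status_b="known", ref_gene_id=gid)
        for _ in range(self.cfg.n_c):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            t = self.iso(chrom, strand, pairs[1:3], self.pick_tissues(2))
            self._truth_transcript(t, "class_c", class_a="c", class_b="c",
                                   status_a="known", status_b="known", ref_gene_id=gid)
        for _ in range(self.cfg.n_k):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            last_end = pairs[-1][1]
            ext = pairs + [(last_end + 400, last_end + 700)]
            t = self.iso(chrom, strand, ext, self.pick_tissues(2))
            self._truth_transcript(t, "class_k", class_a="k", class_b="k",
                                   status_a="known", status_b="known", ref_gene_id=gid)
        for _ in range(self.cfg.n_o):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            t = self.iso(chrom, strand, [(base + 1100, base + 1500)], self.pick_tissues(2))
            self._plant_window(t, "C" * 30)
            self._truth_transcript(t, "class_o", class_a="o", class_b="o",
                                   status_a="known", status_b="known", ref_gene_id=gid)
        for _ in range(self.cfg.n_s):
            chrom, base, strand = self.next_slot()
            anti = "-" if strand == "+" else "+"
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            # antisense 2-exon model sharing the position of reference intron 2
            t = self.iso(
                chrom, anti,
                [(base + 1750, base + 1900), (base + 2400, base + 2550)],
                self.pick_tissues(2),
            )
            self._truth_transcript(t, "class_s", class_a="s", class_b="s",
                                   status_a="novel_intergenic", status_b="novel_intergenic",
                                   ref_gene_id=gid)
        for _ in range(self.cfg.n_x):
            chrom, base, strand = self.next_slot()
            anti = "-" if strand == "+" else "+"
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            t = self.iso(chrom, anti, [(base + 1050, base + 1350)], self.pick_tissues(2))
            self._plant_window(t, "C" * 30)
            self._truth_transcript(t, "class_x", class_a="x", class_b="x",
                                   status_a="novel_intergenic", status_b="novel_intergenic",
                                   ref_gene_id=gid)
        for _ in range(self.cfg.n_i):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            t = self.iso(chrom, strand, [(base + 1300, base + 1600)], self.pick_tissues(2))
            self._plant_window(t, "C" * 30)
            self._truth_transcript(t, "class_i", class_a="i", class_b="i",
                                   status_a="novel_intragenic", status_b="novel_intragenic",
                                   ref_gene_id=gid)
        for _ in range(self.cfg.n_y):
            chrom, base, strand = self.next_slot()
            gid = self.ref_gene(chrom, base, strand, [(base + 2500, base + 2800)])
            t = self.iso(
                chrom, strand,
                [(base + 1000, base + 1200), (base + 4800, base + 5000)],
                self.pick_tissues(2),
            )
            self._truth_transcript(t, "class_y", class_a="y", class_b="y",
                                   status_a="novel_intergenic", status_b="novel_intergenic",
                                   ref_gene_id=gid)
        for _ in range(self.cfg.n_u):
            chrom, base, strand = self.next_slot()
            t = self.iso(
                chrom, strand,
                [(base + 1000, base + 1200), (base + 1700, base + 1900)],
                self.pick_tissues(2),
            )
            self._truth_transcript(t, "class_u", class_a="u", class_b="u",
                                   status_a="novel_intergenic", status_b="novel_intergenic")
        for _ in range(self.cfg.n_fused):
            chrom, base, strand = self.next_slot()
            g1_pairs = [(base + 500, base + 700), (base + 1200, base + 1400)]
            g2_pairs = [(base + 4000, base + 4200), (base + 4700, base + 4900)]
            g1 = self.ref_gene(chrom, base, strand, g1_pairs)
            g2 = self.ref_gene(chrom, base, strand, g2_pairs)
            t = self.iso(chrom, strand, g1_pairs + g2_pairs, self.pick_tissues(2))
            self._truth_transcript(
                t, "fused", class_a="k", class_b="k",
                status_a="known", status_b="known", ref_gene_id=g1,
                partner_gene_ids=f"{g1},{g2}",
            )

    def plant_biotypes(self) -> None:
        # premature-stop models at configured distances from the final junction
        for offset in self.cfg.nmd_offsets:
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            t = self.iso(chrom, strand, pairs, self.pick_tissues(2))
            seq = self._orf_sequence(t.spliced_length, t, offset)
            self.write_spliced_sequence(t, seq)
            biotype = "NMD" if offset > 50 else "protein_coding"
            self._truth_transcript(
                t, f"nmd_offset_{offset}", class_a="=", class_b="=",
                status_a="known", status_b="known", biotype=biotype,
                ref_gene_id=gid, value=float(offset),
            )
        for _ in range(self.cfg.n_coding):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            t = self.iso(chrom, strand, pairs, self.pick_tissues(2))
            seq = self._orf_sequence(t.spliced_length, t, -150)
            self.write_spliced_sequence(t, seq)
            self._truth_transcript(t, "coding", class_a="=", class_b="=",
                                   status_a="known", status_b="known",
                                   biotype="protein_coding", ref_gene_id=gid)
        for _ in range(self.cfg.n_lncrna):
            chrom, base, strand = self.next_slot()
            pairs = [(base + 1000, base + 1150), (base + 1650, base + 1800)]
            t = self.iso(chrom, strand, pairs, self.pick_tissues(2))
            self.write_spliced_sequence(t, "C" * t.spliced_length)
            self._truth_transcript(t, "lncrna", class_a="u", class_b="u",
                                   status_a="novel_intergenic", status_b="novel_intergenic",
                                   biotype="lncRNA")
        for _ in range(self.cfg.n_short_noncoding):
            chrom, base, strand = self.next_slot()
            t = self.iso(chrom, strand, [(base + 1000, base + 1150)], self.pick_tissues(2))
            self.write_spliced_sequence(t, "C" * t.spliced_length)
            self._plant_window(t, "C" * 30)
            self._truth_transcript(t, "short_noncoding", class_a="u", class_b="u",
                                   status_a="novel_intergenic", status_b="novel_intergenic",
                                   biotype="short_noncoding")

    @staticmethod
    def _orf_sequence(total_len: int, t: TranscriptModel, stop_offset: int) -> str:
        """Spliced sequence whose single ORF's stop ends ``stop_offset`` nt
        upstream of the final splice junction (negative: downstream)."""
        from .biotype import final_junction_spliced_position

        junction = final_junction_spliced_position(t)
        assert junction is not None
        orf_len = 300
        orf_end = junction - stop_offset
        orf_start = orf_end - orf_len
        if orf_start < 0 or orf_end > total_len:
            raise ValueError("ORF does not fit the planted transcript")
        n_mid = (orf_len - 6) // 3
        seq = (
            "C" * orf_start
            + "ATG"
            + "CAC" * n_mid
            + "TAA"
            + "C" * (total_len - orf_end)
        )
        assert len(seq) == total_len
        return seq

    def _plant_window(self, t: TranscriptModel, window: str) -> None:
        """Write the 30-nt window scanned by the poly(A) filter (on the
        transcript's own strand) into the genome."""
        if t.strand == "+":
            self.write_seq(t.chrom, t.end, window)
        else:
            self.write_seq(t.chrom, t.start - len(window), revcomp(window))

    def plant_contamination(self) -> None:
        for _ in range(self.cfg.n_gdna):
            chrom, base, strand = self.next_slot()
            t = self.iso(chrom, strand, [(base + 1000, base + 1600)], self.pick_tissues(1))
            self._plant_window(t, "A" * 30)
            self._truth_transcript(t, "gdna", removed_by="gdna")
        for _ in range(self.cfg.n_polya_controls):
            chrom, base, strand = self.next_slot()
            t = self.iso(chrom, strand, [(base + 1000, base + 1600)], self.pick_tissues(2))
            # every 20-mer of this window carries 2 mismatches: below threshold
            self._plant_window(t, "A" * 10 + "C" + "A" * 8 + "C" + "A" * 10)
            self._truth_transcript(t, "polya_control", class_a="u", class_b="u",
                                   status_a="novel_intergenic", status_b="novel_intergenic")
        for _ in range(self.cfg.n_singleton_monoexons):
            chrom, base, strand = self.next_slot()
            t = self.iso(chrom, strand, [(base + 1000, base + 1400)], self.pick_tissues(1))
            self._plant_window(t, "C" * 30)
            self._truth_transcript(t, "singleton_monoexon", removed_by="singleton")

    def plant_rescue(self) -> None:
        tissues = self.cfg.tissues
        for i in range(self.cfg.n_rescue):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            source = tissues[i % len(tissues)]
            target = tissues[(i + 1) % len(tissues)]
            t = self.iso(chrom, strand, pairs, frozenset({source}))
            self.support_junctions(target, t)
            self.expression.set(t.transcript_id, target, self.cfg.rescue_fpkm)
            self._truth_transcript(
                t, "rescue", class_a="=", class_b="=",
                status_a="known", status_b="known", ref_gene_id=gid,
                detection=f"{source}:longread;{target}:rescued",
            )
        for i in range(self.cfg.n_rescue_junction_controls):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            source = tissues[i % len(tissues)]
            target = tissues[(i + 1) % len(tissues)]
            t = self.iso(chrom, strand, pairs, frozenset({source}))
            self.support_junctions(target, t, skip_index=1)
            self.expression.set(t.transcript_id, target, self.cfg.rescue_fpkm)
            self._truth_transcript(
                t, "rescue_control_junction", class_a="=", class_b="=",
                status_a="known", status_b="known", ref_gene_id=gid,
                detection=f"{source}:longread",
            )
        for i in range(self.cfg.n_rescue_fpkm_controls):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            source = tissues[i % len(tissues)]
            target = tissues[(i + 1) % len(tissues)]
            t = self.iso(chrom, strand, pairs, frozenset({source}))
            self.support_junctions(target, t)
            self.expression.set(t.transcript_id, target, self.cfg.rescue_control_fpkm)
            self._truth_transcript(
                t, "rescue_control_fpkm", class_a="=", class_b="=",
                status_a="known", status_b="known", ref_gene_id=gid,
                detection=f"{source}:longread",
            )

    def plant_as_events(self) -> None:
        layouts = {
            "SE": (
                [(1000, 1200), (1700, 1900), (2400, 2600)],
                [(1000, 1200), (2400, 2600)],
            ),
            "A5E": (
                [(1000, 1200), (1700, 1900)],
                [(1000, 1230), (1700, 1900)],
            ),
            "A3E": (
                [(1000, 1200), (1700, 1900)],
                [(1000, 1200), (1730, 1900)],
            ),
            "AFE": (
                [(1000, 1200), (1900, 2100)],
                [(1400, 1600), (1900, 2100)],
            ),
            "ALE": (
                [(1000, 1200), (1700, 1900)],
                [(1000, 1200), (2200, 2400)],
            ),
            "MXE": (
                [(1000, 1200), (1700, 1800), (2300, 2500)],
                [(1000, 1200), (1950, 2050), (2300, 2500)],
            ),
            "IR": (
                [(1000, 1100), (1200, 1300), (1400, 1500)],
                [(1000, 1300), (1400, 1500)],
            ),
        }
        for etype, (p1, p2) in layouts.items():
            chrom, base, _ = self.next_slot()
            strand = "+"  # layouts are written in plus-strand orientation
            tissues = self.pick_tissues(2)
            t1 = self.iso(chrom, strand, [(base + s, base + e) for s, e in p1], tissues)
            t2 = self.iso(chrom, strand, [(base + s, base + e) for s, e in p2], tissues)
            n_events = 0 if etype == "IR" else 1
            n_ir = 1 if etype == "IR" else 0
            self.truth.add(
                object_id=t1.transcript_id,
                kind="as_gene",
                role=f"as_{etype}",
                chrom=chrom,
                strand=strand,
                event_type=etype,
                n_events=n_events,
                n_ir_events=n_ir,
                partner_gene_ids=t2.transcript_id,
            )
            for t in (t1, t2):
                self._truth_transcript(t, f"as_{etype}_member", class_a="u", class_b="u",
                                       status_a="novel_intergenic",
                                       status_b="novel_intergenic")

    def plant_extensions(self) -> None:
        read_len = self.cfg.three_prime_read_length

        def five_prime_extend(pairs, strand, L):
            vp = [list(p) for p in pairs]
            (vp[0] if strand == "+" else vp[-1])[0 if strand == "+" else 1] += (
                -L if strand == "+" else L
            )
            return [tuple(p) for p in vp]

        def three_prime_extend(pairs, strand, L):
            vp = [list(p) for p in pairs]
            (vp[-1] if strand == "+" else vp[0])[1 if strand == "+" else 0] += (
                L if strand == "+" else -L
            )
            return [tuple(p) for p in vp]

        # --- 5' extensions with CAGE verdict planting
        cage_plan = ["iso_only", "both", "ref_only", "untestable"]
        for i, L in enumerate(self.cfg.ext5_lengths):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            ext_pairs = five_prime_extend(pairs, strand, L)
            t = self.iso(chrom, strand, ext_pairs, self.pick_tissues(2))
            verdict = cage_plan[i % len(cage_plan)]
            iso_tss = t.start if strand == "+" else t.end
            ref_tss = pairs[0][0] if strand == "+" else pairs[-1][1]
            third = L // 3
            unique = verdict != "untestable"

            def tag_at(pos: int, unique_flag: bool) -> None:
                if strand == "+":
                    iv = GenomicInterval(chrom, pos, pos + 25, "+")
                else:
                    iv = GenomicInterval(chrom, pos - 24, pos + 1, "-")
                self.cage.append(BedRead(iv, self.new_read_name(), unique_flag))

            if verdict in ("iso_only", "both", "untestable"):
                tag_at(iso_tss if strand == "+" else iso_tss - 1, unique)
            if verdict in ("ref_only", "both"):
                tag_at(ref_tss if strand == "+" else ref_tss - 1, unique)
            self._truth_transcript(
                t, "ext5", class_a="=", class_b="=",
                status_a="known", status_b="known", ref_gene_id=gid,
                ext5=L, ext3=0, cage_verdict=verdict,
            )

        # --- 3' extensions with contained / straddling 3'-read planting
        for i, L in enumerate(self.cfg.ext3_lengths):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            ext_pairs = three_prime_extend(pairs, strand, L)
            t = self.iso(chrom, strand, ext_pairs, self.pick_tissues(2))
            validated = i % 2 == 0
            ref_3p = pairs[-1][1] if strand == "+" else pairs[0][0]
            if validated:
                for k in range(2):
                    if strand == "+":
                        s = ref_3p + 10 + k * 20
                        iv = GenomicInterval(chrom, s, s + read_len, "+")
                    else:
                        e = ref_3p - 10 - k * 20
                        iv = GenomicInterval(chrom, e - read_len, e, "-")
                    self.three_prime.append(BedRead(iv, self.new_read_name(), True))
            else:
                # read straddling the reference 3' boundary: never supports
                if strand == "+":
                    iv = GenomicInterval(chrom, ref_3p - read_len // 2,
                                         ref_3p + read_len // 2, "+")
                else:
                    iv = GenomicInterval(chrom, ref_3p - read_len // 2,
                                         ref_3p + read_len // 2, "-")
                self.three_prime.append(BedRead(iv, self.new_read_name(), True))
            if i == 0:
                # expression-gain case: reads in exons shared with the
                # reference model plus the extension reads above (the
                # extended terminal exon is the genomic last on '+', the
                # genomic first on '-')
                shared_idx = (
                    list(range(t.n_exons - 1))
                    if strand == "+"
                    else list(range(1, t.n_exons))
                )
                for k in range(self.cfg.n_gain_shared_reads):
                    ex = t.exons[shared_idx[k % len(shared_idx)]]
                    s = ex.start + 5 + (k * 13) % max(1, len(ex) - read_len - 10)
                    iv = GenomicInterval(chrom, s, s + read_len, strand)
                    self.three_prime.append(BedRead(iv, self.new_read_name(), True))
                extra = self.cfg.n_gain_extension_reads - 2
                for k in range(extra):
                    if strand == "+":
                        s = ref_3p + 60 + k * 25
                        iv = GenomicInterval(chrom, s, s + read_len, "+")
                    else:
                        e = ref_3p - 60 - k * 25
                        iv = GenomicInterval(chrom, e - read_len, e, "-")
                    self.three_prime.append(BedRead(iv, self.new_read_name(), True))
                n_iso = self.cfg.n_gain_shared_reads + self.cfg.n_gain_extension_reads
                gain = float(np.log2(n_iso / self.cfg.n_gain_shared_reads))
                role = "ext3_gain"
                value = gain
            else:
                role, value = "ext3", None
            self._truth_transcript(
                t, role, class_a="=", class_b="=",
                status_a="known", status_b="known", ref_gene_id=gid,
                ext5=0, ext3=L, three_prime_validated=validated, value=value,
            )

        # --- both-end extensions; first fully validated incl. ChIP
        for i, (L5, L3) in enumerate(self.cfg.ext_both_lengths):
            chrom, base, strand = self.next_slot()
            pairs = self.std_pairs(base)
            gid = self.ref_gene(chrom, base, strand, pairs)
            ext_pairs = three_prime_extend(five_prime_extend(pairs, strand, L5), strand, L3)
            t = self.iso(chrom, strand, ext_pairs, self.pick_tissues(2))
            validated = i == 0
            if validated:
                tss = t.start if strand == "+" else t.end
                prom_lo = tss - 400 if strand == "+" else tss - 100
                for sample in ("s1", "s2"):
                    self.peaks.append(
                        Peak(GenomicInterval(chrom, max(0, prom_lo), prom_lo + 300),
                             "H3K4me3", sample, True)
                    )
                    self.peaks.append(
                        Peak(GenomicInterval(chrom, t.start + 200, t.start + 1200),
                             "H3K36me3", sample, True)
                    )
                ref_3p = pairs[-1][1] if strand == "+" else pairs[0][0]
                if strand == "+":
                    iv = GenomicInterval(chrom, ref_3p + 20, ref_3p + 20 + read_len, "+")
                else:
                    iv = GenomicInterval(chrom, ref_3p - 20 - read_len, ref_3p - 20, "-")
                self.three_prime.append(BedRead(iv, self.new_read_name(), True))
                iso_tss = t.start if strand == "+" else t.end
                if strand == "+":
                    civ = GenomicInterval(chrom, iso_tss, iso_tss + 25, "+")
                else:
                    civ = GenomicInterval(chrom, iso_tss - 25, iso_tss, "-")
                self.cage.append(BedRead(civ, self.new_read_name(), True))
            self._truth_transcript(
                t, "ext_both", class_a="=", class_b="=",
                status_a="known", status_b="known", ref_gene_id=gid,
                ext5=L5, ext3=L3,
                chip_promoter=validated if validated else None,
                chip_body=validated if validated else None,
                three_prime_validated=validated,
                cage_verdict="iso_only" if validated else None,
            )

    def plant_chip_validation(self) -> None:
        """Novel intergenic genes with planted promoter/body peaks,
        including exact 1-bp-overlap boundary cases."""
        plans = [
            ("chip_full", True, True),
            ("chip_full", True, True),
            ("chip_boundary", True, False),
            ("chip_none", False, False),
        ]
        for role, want_prom, want_body in plans:
            chrom, base, strand = self.next_slot()
            pairs = [(base + 2000, base + 2200), (base + 2700, base + 2900)]
            t = self.iso(chrom, strand, pairs, frozenset({self.cfg.tissues[1]}) |
                         frozenset({self.cfg.tissues[0]}))
            tss = base + 2000 if strand == "+" else base + 2900
            prom_start = tss - 500 if strand == "+" else tss - 100
            prom_end = tss + 100 if strand == "+" else tss + 500
            if role == "chip_full":
                for sample in ("s1", "s2"):
                    self.peaks.append(
                        Peak(GenomicInterval(chrom, prom_start + 100, prom_start + 400),
                             "H3K4me3", sample, True)
                    )
                    self.peaks.append(
                        Peak(GenomicInterval(chrom, base + 2100, base + 2800),
                             "H3K36me3", sample, True)
                    )
            elif role == "chip_boundary":
                # H3K4me3 overlapping the promoter window by exactly 1 bp;
                # H3K36me3 abutting the gene body with zero overlap
                self.peaks.append(
                    Peak(GenomicInterval(chrom, prom_start - 299, prom_start + 1),
                         "H3K4me3", "s1", True)
                )
                self.peaks.append(
                    Peak(GenomicInterval(chrom, base + 1500, base + 2000),
                         "H3K36me3", "s1", True)
                )
            self._truth_transcript(
                t, role, class_a="u", class_b="u",
                status_a="novel_intergenic", status_b="novel_intergenic",
                chip_promoter=want_prom, chip_body=want_body,
            )

    # -----------------------------------------------------------------------

    def _truth_transcript(self, t: TranscriptModel, role: str, **kwargs) -> None:
        detection = kwargs.pop(
            "detection",
            ";".join(f"{tissue}:longread" for tissue in sorted(t.source_tissues)),
        )
        self.truth.add(
            object_id=t.transcript_id,
            kind="transcript",
            role=role,
            chrom=t.chrom,
            strand=t.strand,
            detection=detection,
            **kwargs,
        )

    def _plant_splice_motifs(self) -> int:
        """Write canonical GT..AG motifs (strand-aware) for planted introns;
        then scramble a configured fraction of long-read-only introns.
        Returns the number of non-canonical long-read introns planted."""
        claimed: dict[tuple[str, int], str] = {}

        def write_motif(chrom: str, donor: int, acceptor: int, strand: str,
                        d_motif: str, a_motif: str) -> bool:
            if strand == "+":
                targets = [(donor, d_motif[0]), (donor + 1, d_motif[1]),
                           (acceptor - 2, a_motif[0]), (acceptor - 1, a_motif[1])]
            else:
                rd, ra = revcomp(d_motif), revcomp(a_motif)
                targets = [(acceptor - 2, rd[0]), (acceptor - 1, rd[1]),
                           (donor, ra[0]), (donor + 1, ra[1])]
            for pos, basech in targets:
                prev = claimed.get((chrom, pos))
                if prev is not None and prev != basech:
                    return False
            for pos, basech in targets:
                claimed[(chrom, pos)] = basech
                self.arrays[chrom][pos] = basech
            return True

        ref_junctions: set[tuple[str, int, int, str]] = set()
        for t in self.ref_a + self.ref_b:
            for d, a in t.intron_chain:
                ref_junctions.add((t.chrom, d, a, t.strand))
        for chrom, d, a, strand in sorted(ref_junctions):
            write_motif(chrom, d, a, strand, "GT", "AG")

        iso_only: list[tuple[str, int, int, str]] = []
        seen: set[tuple[str, int, int, str]] = set()
        for t in self.transcripts:
            for d, a in t.intron_chain:
                key = (t.chrom, d, a, t.strand)
                if key in seen:
                    continue
                seen.add(key)
                if key in ref_junctions:
                    continue
                iso_only.append(key)
        written = [
            key for key in sorted(iso_only)
            if write_motif(key[0], key[1], key[2], key[3], "GT", "AG")
        ]

        # deliberate non-canonical fraction among exclusive long-read introns
        pos_use: dict[tuple[str, int], int] = defaultdict(int)
        all_juncs = sorted(ref_junctions | set(written))
        for chrom, d, a, strand in all_juncs:
            for pos in (d, d + 1, a - 2, a - 1):
                pos_use[(chrom, pos)] += 1
        exclusive = [
            key for key in written
            if all(pos_use[(key[0], p)] == 1 for p in (key[1], key[1] + 1, key[2] - 2, key[2] - 1))
        ]
        rng = self._rng("noncanonical")
        n_scramble = int(round(self.cfg.non_canonical_fraction * len(seen)))
        n_scramble = min(n_scramble, len(exclusive))
        idx = sorted(rng.choice(len(exclusive), size=n_scramble, replace=False)) if n_scramble else []
        for i in idx:
            chrom, d, a, strand = exclusive[i]
            if strand == "+":
                self.arrays[chrom][d], self.arrays[chrom][d + 1] = "C", "C"
                self.arrays[chrom][a - 2], self.arrays[chrom][a - 1] = "G", "G"
            else:
                self.arrays[chrom][d], self.arrays[chrom][d + 1] = "C", "C"
                self.arrays[chrom][a - 2], self.arrays[chrom][a - 1] = "G", "G"
        return n_scramble

    def _apply_dropout(self) -> None:
        rate = self.cfg.junction_dropout
        if rate <= 0:
            return
        rng = self._rng("dropout")
        kept = {}
        for key in sorted(
            self.junctions._counts,
            key=lambda kv: (kv[0], kv[1].chrom, kv[1].donor, kv[1].acceptor, kv[1].strand),
        ):
            u = rng.uniform()
            if u >= rate:
                kept[key] = self.junctions._counts[key]
        self.junctions._counts = kept

    def build(self) -> SimBundle:
        self.plant_exact()
        self.plant_refb_only()
        self.plant_structural()
        self.plant_biotypes()
        self.plant_contamination()
        self.plant_rescue()
        self.plant_as_events()
        self.plant_extensions()
        self.plant_chip_validation()
        self._flush_support()
        self._apply_dropout()
        n_noncanonical = self._plant_splice_motifs()
        self.truth.add(
            object_id="catalogue", kind="summary", role="non_canonical_junctions",
            value=float(n_noncanonical),
        )
        genome = {c: "".join(self.arrays[c]) for c in self.chroms}
        refs = {
            "refA": group_by_gene_id(self.ref_a, "refA"),
            "refB": group_by_gene_id(self.ref_b, "refB"),
        }
        return SimBundle(
            config=self.cfg,
            genome=genome,
            references=refs,
            transcripts=sorted(
                self.transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)
            ),
            tissue_variants=self.tissue_variants,
            junction_support=self.junctions,
            expression=self.expression,
            peaks=PeakSet(self.peaks),
            three_prime_reads=self.three_prime,
            cage_tags=self.cage,
            truth=self.truth,
        )


def simulate(config: SimulationConfig | None = None, out_dir=None) -> SimBundle:
    """Generate a synthetic bundle; optionally write it to ``out_dir``."""
    bundle = _Builder(config or SimulationConfig()).build()
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
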