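"""End-to-end orchestration: filter -> merge -> classify -> detect ->
biotype -> events -> borders -> validate, with tabular report output.

The stages run in a fixed order on one input bundle (per-tissue long-read
GTFs, one or two reference GTFs, genome FASTA, junction-support and FPKM
tables, optional peak/read/tag BEDs) and the report directory receives one
TSV per result family plus a parameter log.  Every run with the same
inputs and parameters produces byte-identical outputs.
"""

from __future__ import annotations

import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import borders as bd
from .annotation import (
    AnnotationSet,
    TranscriptModel,
    canonical_splice_fraction,
    cluster_genes,
    read_gtf,
    write_gtf,
)
from .biotype import (
    BiotypeCall,
    DEFAULT_EVALUE_CUTOFF,
    DEFAULT_MIN_ORF_NT,
    DEFAULT_START_CODONS,
    classify_catalogue_biotypes,
    gene_biotype,
    load_homology_tsv,
)
from .classify import (
    ClassifierConfig,
    KNOWN_CODES,
    assign_gene_status,
    classify_catalogue,
    combined_membership,
    detect_fused_transcripts,
)
from .contamination import (
    MergeConfig,
    PolyAFilterConfig,
    drop_singleton_monoexons,
    filter_genomic_polyA,
    merge_transcripts,
)
from .detection import (
    DEFAULT_FPKM_THRESHOLD,
    ExpressionTable,
    JunctionSupportTable,
    build_detection_matrix,
    estimate_inflection_threshold,
    summarize_tissues,
)
from .splice_events import AS_EVENT_TYPES, catalogue_events, candidate_genes


@dataclass
class PipelineParams:
    """Every tunable constant of the pipeline, surfaced and defaulted."""

    polya_run_length: int = 20
    polya_max_mismatch: int = 1
    polya_window: int = 30
    junction_fuzz: int = 5
    ignore_5prime_difference: bool = True
    mono_min_reciprocal_overlap: float = 0.5
    fpkm_threshold: float = DEFAULT_FPKM_THRESHOLD
    estimate_threshold: bool = False
    min_junction_reads: int = 1
    min_orf_length: int = DEFAULT_MIN_ORF_NT
    start_codons: tuple[str, ...] = tuple(sorted(DEFAULT_START_CODONS))
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF


@dataclass
class PipelineConfig:
    """Input locations, output directory and parameters of one run."""

    tissue_gtfs: dict[str, str]
    reference_gtfs: dict[str, str]
    genome_fasta: str
    junctions_tsv: str
    fpkm_tsv: str
    out_dir: str
    peaks_bed: str | None = None
    three_prime_bed: str | None = None
    cage_bed: str | None = None
    homology_tsv: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return PipelineConfig(params=params, **raw)

    @staticmethod
    def for_bundle_dir(bundle_dir: str, out_dir: str,
                       params: PipelineParams | None = None,
                       tissues: tuple[str, ...] | None = None) -> "PipelineConfig":
        """Config pointing at the standard synthetic-bundle layout."""
        if tissues is None:
            tissues = tuple(
                sorted(
                    f.removeprefix("isoseq_").removesuffix(".gtf")
                    for f in os.listdir(bundle_dir)
                    if f.startswith("isoseq_") and f.endswith(".gtf")
                )
            )
        refs = {
            f.removeprefix("ref_").removesuffix(".gtf"): os.path.join(bundle_dir, f)
            for f in sorted(os.listdir(bundle_dir))
            if f.startswith("ref_") and f.endswith(".gtf")
        }
        j = os.path.join
        return PipelineConfig(
            tissue_gtfs={t: j(bundle_dir, f"isoseq_{t}.gtf") for t in tissues},
            reference_gtfs=refs,
            genome_fasta=j(bundle_dir, "genome.fa"),
            junctions_tsv=j(bundle_dir, "junctions.tsv"),
            fpkm_tsv=j(bundle_dir, "fpkm.tsv"),
            peaks_bed=j(bundle_dir, "peaks.bed"),
            three_prime_bed=j(bundle_dir, "three_prime_reads.bed"),
            cage_bed=j(bundle_dir, "cage_tags.bed"),
            out_dir=out_dir,
            params=params or PipelineParams(),
        )


@dataclass
class PipelineResult:
    catalogue: AnnotationSet
    removed: dict[str, list[TranscriptModel]]
    classifications: dict[str, dict]  # ref label -> {tid -> ClassCode}
    gene_status: dict[str, dict]  # gene_id -> {ref label -> GeneStatus}
    membership: dict[str, str]
    fused: dict[str, dict[str, list[str]]]  # ref label -> {tid -> gene ids}
    biotypes: dict[str, BiotypeCall]
    gene_biotypes: dict[str, str]
    threshold_used: float
    matrix: object
    tissue_summary: object
    events: dict[str, object]
    extensions: list[bd.ExtensionRecord]
    splice_report: object


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_genome(path):
    import pyfaidx

    return pyfaidx.Fasta(path, sequence_always_upper=True)


def run(config: PipelineConfig) -> PipelineResult:
    """Run all stages and write the report bundle to ``config.out_dir``."""
    p = config.params
    log: list[str] = []

    def stage(name):
        log.append(f"stage: {name}")
        return name

    try:
        stage("load")
        genome = _load_genome(config.genome_fasta)
        references = {
            label: read_gtf(path, label)
            for label, path in sorted(config.reference_gtfs.items())
        }
        pool: list[TranscriptModel] = []
        for tissue, path in sorted(config.tissue_gtfs.items()):
            for t in read_gtf(path, tissue).transcripts():
                pool.append(t.with_(gene_id="", source_tissues=frozenset({tissue})))
        junctions = JunctionSupportTable.from_tsv(config.junctions_tsv)
        expression = ExpressionTable.from_tsv(config.fpkm_tsv)
        peaks = bd.PeakSet.from_bed(config.peaks_bed) if config.peaks_bed else None
        reads3p = bd.read_bed6(config.three_prime_bed) if config.three_prime_bed else None
        cage = bd.read_bed6(config.cage_bed) if config.cage_bed else None
        homology = load_homology_tsv(config.homology_tsv) if config.homology_tsv else None
        tissues = tuple(sorted(config.tissue_gtfs))
    except Exception as e:  # pragma: no cover - error path
        raise PipelineError("load", e) from e

    try:
        stage("filter_genomic_polyA")
        polya_cfg = PolyAFilterConfig(
            p.polya_run_length, p.polya_max_mismatch, p.polya_window
        )
        log.append(
            f"polyA filter: run>={polya_cfg.run_length}, "
            f"mismatch<={polya_cfg.max_mismatch}, window={polya_cfg.window}"
        )
        # flag on the raw per-tissue models; a model is an artifact if any
        # tissue observation of it is flagged
        kept_pool, flagged = filter_genomic_polyA(pool, genome, polya_cfg)
        flagged_ids = {t.transcript_id for t in flagged}
        kept_pool = [t for t in kept_pool if t.transcript_id not in flagged_ids]
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("filter_genomic_polyA", e) from e

    try:
        stage("merge")
        merge_cfg = MergeConfig(
            p.junction_fuzz, p.ignore_5prime_difference, p.mono_min_reciprocal_overlap
        )
        log.append(
            f"merge: fuzz={merge_cfg.junction_fuzz}, "
            f"ignore_5prime={merge_cfg.ignore_5prime_difference}, "
            f"mono_overlap>={merge_cfg.mono_min_reciprocal_overlap}"
        )
        merged = merge_transcripts(kept_pool, merge_cfg)
        kept, singletons = drop_singleton_monoexons(merged)
        catalogue = cluster_genes(kept, source_label="isoseq", gene_prefix="ISOG")
    except Exception as e:
        raise PipelineError("merge", e) from e

    try:
        stage("classify")
        cls_cfg = ClassifierConfig(p.mono_min_reciprocal_overlap)
        classifications = classify_catalogue(catalogue, references, cls_cfg)
        gene_status = {
            g.gene_id: assign_gene_status(g, classifications)
            for g in catalogue.genes
        }
        membership = {
            gid: combined_membership(statuses) for gid, statuses in gene_status.items()
        }
        fused = {
            label: detect_fused_transcripts(catalogue.transcripts(), ref)
            for label, ref in references.items()
        }
    except Exception as e:
        raise PipelineError("classify", e) from e

    try:
        stage("detect")
        threshold = p.fpkm_threshold
        if p.estimate_threshold:
            multi = [
                expression.fpkm(t.transcript_id, ts)
                for t in catalogue.transcripts()
                if len(t.source_tissues) > 1
                for ts in t.source_tissues
            ]
            threshold = estimate_inflection_threshold(multi, default=p.fpkm_threshold)
        log.append(
            f"detection: fpkm>{threshold:g}, "
            f"min_junction_reads={p.min_junction_reads}"
        )
        matrix = build_detection_matrix(
            catalogue, tissues, junctions, expression, threshold, p.min_junction_reads
        )
        tissue_summary = summarize_tissues(matrix, catalogue)
    except Exception as e:
        raise PipelineError("detect", e) from e

    try:
        stage("biotype")
        log.append(
            f"biotype: min_orf={p.min_orf_length}nt, "
            f"start_codons={','.join(p.start_codons)}, NMD>50nt, lncRNA>200nt"
        )
        biotypes = classify_catalogue_biotypes(
            catalogue, genome, homology,
            frozenset(p.start_codons), p.min_orf_length,
        )
        gene_biotypes = {
            g.gene_id: gene_biotype(biotypes[t.transcript_id] for t in g.transcripts)
            for g in catalogue.genes
        }
    except Exception as e:
        raise PipelineError("biotype", e) from e

    try:
        stage("splice_events")
        events = catalogue_events(catalogue)
    except Exception as e:
        raise PipelineError("splice_events", e) from e

    try:
        stage("borders")
        extensions = _border_stage(
            catalogue, references, classifications, gene_status,
            peaks, reads3p, cage,
        )
    except Exception as e:
        raise PipelineError("borders", e) from e

    try:
        stage("report")
        splice_report = canonical_splice_fraction(catalogue, genome)
        result = PipelineResult(
            catalogue=catalogue,
            removed={"gdna": flagged, "singleton": singletons},
            classifications=classifications,
            gene_status=gene_status,
            membership=membership,
            fused=fused,
            biotypes=biotypes,
            gene_biotypes=gene_biotypes,
            threshold_used=threshold,
            matrix=matrix,
            tissue_summary=tissue_summary,
            events=events,
            extensions=extensions,
            splice_report=splice_report,
        )
        _write_report(config, result, log)
    except Exception as e:
        raise PipelineError("report", e) from e
    return result


def best_reference_gene(gene, codes: dict) -> str | None:
    """Modal best-match reference gene over members with known-class codes."""
    votes = Counter()
    for t in gene.transcripts:
        cc = codes.get(t.transcript_id)
        if cc is not None and cc.code in KNOWN_CODES and cc.ref_gene_id:
            votes[cc.ref_gene_id] += 1
    if not votes:
        return None
    top = max(votes.values())
    return sorted(g for g, n in votes.items() if n == top)[0]


def _border_stage(
    catalogue, references, classifications, gene_status, peaks, reads3p, cage
) -> list[bd.ExtensionRecord]:
    records: list[bd.ExtensionRecord] = []
    for label, ref in sorted(references.items()):
        codes = classifications[label]
        for gene in catalogue.genes:
            if gene_status[gene.gene_id][label].status != "known":
                continue
            ref_gid = best_reference_gene(gene, codes)
            if ref_gid is None:
                continue
            ref_gene = next(g for g in ref.genes if g.gene_id == ref_gid)
            if ref_gene.chrom != gene.chrom or ref_gene.strand != gene.strand:
                continue
            rec = bd.detect_extension(gene, ref_gene, label)
            if peaks is not None:
                chip = bd.validate_chip(gene, peaks)
                rec.chip_promoter = chip.chip_promoter
                rec.chip_body = chip.chip_body
                rec.chip_all_samples = chip.all_samples_concordant
            if reads3p is not None and rec.ext3_len > 0:
                verdict = bd.validate_3prime(gene, ref_gene, reads3p)
                rec.three_prime_validated = verdict.validated
                rec.three_prime_read_count = verdict.supporting_reads
            if cage is not None and rec.ext5_len > 0:
                pair = bd.cage_candidate_regions(gene, ref_gene)
                rec.cage_verdict = bd.validate_5prime(pair, cage)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# report writing


def _write_report(config: PipelineConfig, r: PipelineResult, log: list[str]) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    j = os.path.join

    write_gtf(r.catalogue, j(out, "catalogue.gtf"))

    pd.DataFrame(
        sorted(
            [(t.transcript_id, reason) for reason, ts in r.removed.items() for t in ts]
        ),
        columns=["transcript_id", "removed_by"],
    ).to_csv(j(out, "removed_transcripts.tsv"), sep="\t", index=False)

    ref_labels = sorted(r.classifications)
    rows = []
    for t in sorted(r.catalogue.transcripts(), key=lambda t: t.transcript_id):
        row = {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "n_exons": t.n_exons,
            "biotype": r.biotypes[t.transcript_id].biotype,
        }
        for label in ref_labels:
            cc = r.classifications[label][t.transcript_id]
            row[f"class_{label}"] = cc.code
            row[f"ref_transcript_{label}"] = cc.ref_transcript_id
            row[f"ref_gene_{label}"] = cc.ref_gene_id
        rows.append(row)
    pd.DataFrame(rows).to_csv(j(out, "classification.tsv"), sep="\t", index=False)

    rows = []
    for g in r.catalogue.genes:
        row = {
            "gene_id": g.gene_id,
            "n_transcripts": len(g.transcripts),
            "gene_biotype": r.gene_biotypes[g.gene_id],
            "membership": r.membership[g.gene_id],
        }
        for label in ref_labels:
            row[f"status_{label}"] = r.gene_status[g.gene_id][label].status
        rows.append(row)
    pd.DataFrame(rows).to_csv(j(out, "gene_status.tsv"), sep="\t", index=False)

    rows = []
    for label in ref_labels:
        counts = Counter(cc.code for cc in r.classifications[label].values())
        for code in "=ckjosxiyu":
            rows.append({"reference": label, "class_code": code, "n_transcripts": counts.get(code, 0)})
    pd.DataFrame(rows).to_csv(j(out, "class_summary.tsv"), sep="\t", index=False)

    r.matrix.to_frame().to_csv(j(out, "detection_matrix.tsv"), sep="\t")
    r.tissue_summary.table.to_csv(
        j(out, "tissue_summary.tsv"), sep="\t", float_format="%.4f"
    )

    rows = []
    for gid in sorted(r.events):
        rep = r.events[gid]
        for ev in rep.events + rep.ir_events:
            rows.append(
                {
                    "gene_id": gid,
                    "event_type": ev.event_type,
                    "coords": ",".join(map(str, ev.coords)),
                    "witnesses": ";".join(ev.witnesses),
                    "counted": ev.event_type != "IR",
                }
            )
    pd.DataFrame(
        rows, columns=["gene_id", "event_type", "coords", "witnesses", "counted"]
    ).to_csv(j(out, "as_events.tsv"), sep="\t", index=False)

    type_counts = Counter()
    n_as_genes = 0
    for rep in r.events.values():
        type_counts.update(rep.counts)
        n_as_genes += rep.is_as_gene
    summary_rows = [
        {"event_type": et, "n_events": type_counts.get(et, 0)} for et in AS_EVENT_TYPES
    ]
    summary_rows.append({"event_type": "IR_detected_not_counted",
                         "n_events": sum(len(rep.ir_events) for rep in r.events.values())})
    summary_rows.append({"event_type": "AS_genes", "n_events": n_as_genes})
    summary_rows.append(
        {"event_type": "candidate_genes", "n_events": len(candidate_genes(r.catalogue))}
    )
    pd.DataFrame(summary_rows).to_csv(j(out, "as_summary.tsv"), sep="\t", index=False)

    rows = []
    for label in ref_labels:
        for tid, gids in sorted(r.fused[label].items()):
            rows.append(
                {"reference": label, "transcript_id": tid, "ref_genes": ",".join(gids)}
            )
    pd.DataFrame(rows, columns=["reference", "transcript_id", "ref_genes"]).to_csv(
        j(out, "fused_transcripts.tsv"), sep="\t", index=False
    )

    rows = []
    for rec in sorted(r.extensions, key=lambda x: (x.ref_source, x.iso_gene_id)):
        rows.append(
            {
                "iso_gene_id": rec.iso_gene_id,
                "ref_source": rec.ref_source,
                "ref_gene_id": rec.ref_gene_id,
                "extension_type": rec.extension_type,
                "ext5_nt": rec.ext5_len,
                "ext3_nt": rec.ext3_len,
                "chip_promoter": rec.chip_promoter,
                "chip_body": rec.chip_body,
                "three_prime_validated": rec.three_prime_validated,
                "three_prime_reads": rec.three_prime_read_count,
                "cage_verdict": rec.cage_verdict,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "iso_gene_id", "ref_source", "ref_gene_id", "extension_type",
            "ext5_nt", "ext3_nt", "chip_promoter", "chip_body",
            "three_prime_validated", "three_prime_reads", "cage_verdict",
        ],
    ).to_csv(j(out, "extensions.tsv"), sep="\t", index=False)

    bd.extension_summary(r.extensions).to_csv(
        j(out, "extension_summary.tsv"), sep="\t", index=False
    )

    frac = r.splice_report.fraction_canonical
    log.append(
        "canonical splice fraction: "
        + ("n/a" if frac is None else f"{frac:.4f} of {r.splice_report.n_introns} introns")
    )
    with open(j(out, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
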