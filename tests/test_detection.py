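"""Detection matrix, short-read rescue rule, knee estimator, summaries."""

import numpy as np
import pytest

from refinery.annotation import Junction, cluster_genes
from refinery.detection import (
    Detection,
    ExpressionTable,
    JunctionSupportTable,
    build_detection_matrix,
    estimate_inflection_threshold,
    is_detected,
    summarize_tissues,
)

from conftest import make_transcript

TISSUES = ("brain", "liver", "spleen")


def support_for(t, tissue, skip=None, count=10):
    table = JunctionSupportTable()
    for i, j in enumerate(t.junctions):
        if skip is not None and i == skip:
            continue
        table.add(tissue, j, count)
    return table


@pytest.fixture
def spliced():
    return make_transcript(
        "t", [(0, 100), (200, 300), (400, 500), (600, 700)], tissues=("brain",)
    )


class TestIsDetected:
    def test_longread_evidence_wins(self, spliced):
        st = is_detected(spliced, "brain", JunctionSupportTable(), ExpressionTable())
        assert st is Detection.LONGREAD

    def test_rescue_needs_all_junctions_and_expression(self, spliced):
        expr = ExpressionTable({("t", "liver"): 0.5})
        st = is_detected(spliced, "liver", support_for(spliced, "liver"), expr)
        assert st is Detection.RESCUED

    def test_below_threshold_expression_blocks_rescue(self, spliced):
        expr = ExpressionTable({("t", "liver"): 0.05})
        st = is_detected(spliced, "liver", support_for(spliced, "liver"), expr)
        assert st is Detection.UNDETECTED

    def test_threshold_comparison_is_strict(self, spliced):
        expr = ExpressionTable({("t", "liver"): 0.1})
        st = is_detected(spliced, "liver", support_for(spliced, "liver"), expr)
        assert st is Detection.UNDETECTED

    def test_missing_junction_blocks_rescue(self, spliced):
        expr = ExpressionTable({("t", "liver"): 5.0})
        st = is_detected(spliced, "liver", support_for(spliced, "liver", skip=1), expr)
        assert st is Detection.UNDETECTED

    def test_mono_exon_rescued_on_expression_alone(self):
        mono = make_transcript("m", [(0, 100)], tissues=("brain",))
        expr = ExpressionTable({("m", "liver"): 0.5})
        st = is_detected(mono, "liver", JunctionSupportTable(), expr)
        assert st is Detection.RESCUED

    def test_unknown_tissue_errors(self, spliced):
        with pytest.raises(ValueError, match="unknown tissue"):
            is_detected(
                spliced, "kidney", JunctionSupportTable(), ExpressionTable(),
                known_tissues=TISSUES,
            )


class TestMonotonicity:
    def test_lowering_threshold_never_shrinks_detection(self, bundle):
        catalogue = cluster_genes(bundle.transcripts, "iso")
        detected = {}
        for thr in (0.2, 0.1, 0.05):
            m = build_detection_matrix(
                catalogue, bundle.config.tissues, bundle.junction_support,
                bundle.expression, threshold=thr,
            )
            detected[thr] = set(m.status)
        assert detected[0.2] <= detected[0.1] <= detected[0.05]

    def test_raising_min_junction_reads_never_grows_detection(self, bundle):
        catalogue = cluster_genes(bundle.transcripts, "iso")
        sets = []
        for mjr in (1, 10, 100):
            m = build_detection_matrix(
                catalogue, bundle.config.tissues, bundle.junction_support,
                bundle.expression, min_junction_reads=mjr,
            )
            sets.append(set(m.status))
        assert sets[2] <= sets[1] <= sets[0]


class TestKneeEstimator:
    def test_piecewise_mixture_knee_near_plateau_start(self):
        # sparse tail below 0.1, dense body above: cumulative-curve vertex
        # (maximum distance to the chord) sits at the density change
        tail = np.logspace(-3, -1, 50)
        body = np.logspace(-1, 2, 450)
        est = estimate_inflection_threshold(np.concatenate([tail, body]))
        assert 0.05 <= est <= 0.2

    def test_constant_values_fall_back_to_default(self):
        assert estimate_inflection_threshold([1.0] * 50) == 0.1

    def test_too_few_values_warn_and_fall_back(self):
        with pytest.warns(UserWarning):
            assert estimate_inflection_threshold([1, 2, 3]) == 0.1


class TestSummaries:
    def _matrix_catalogue(self):
        g1t1 = make_transcript("g1t1", [(0, 100), (200, 300)], tissues=("brain",))
        g1t2 = make_transcript("g1t2", [(0, 100), (200, 350)], tissues=("brain",))
        g2t1 = make_transcript("g2t1", [(1000, 1100), (1200, 1300)],
                               tissues=("brain", "liver"))
        catalogue = cluster_genes([g1t1, g1t2, g2t1], "iso")
        matrix = build_detection_matrix(
            catalogue, TISSUES, JunctionSupportTable(), ExpressionTable()
        )
        return matrix, catalogue

    def test_transcripts_per_gene(self):
        matrix, catalogue = self._matrix_catalogue()
        summary = summarize_tissues(matrix, catalogue)
        brain = summary.table.loc["brain"]
        assert brain["n_detected_genes"] == 2
        assert brain["n_detected_transcripts"] == 3
        assert brain["transcripts_per_gene"] == 1.5
        assert brain["n_from_multi_transcript_genes"] == 2
        assert brain["n_from_single_transcript_genes"] == 1

    def test_tissue_specific_transcripts_and_genes(self):
        matrix, catalogue = self._matrix_catalogue()
        summary = summarize_tissues(matrix, catalogue)
        assert summary.tissue_specific_transcripts["brain"] == ["g1t1", "g1t2"]
        assert summary.tissue_specific_transcripts["liver"] == []
        # the two-tissue transcript's gene is not tissue-specific
        g1 = catalogue.gene_of("g1t1").gene_id
        g2 = catalogue.gene_of("g2t1").gene_id
        assert summary.tissue_specific_genes["brain"] == [g1]
        assert all(g2 not in v for v in summary.tissue_specific_genes.values())

    def test_gene_with_members_specific_to_different_tissues_not_specific(self):
        t1 = make_transcript("a", [(0, 100), (200, 300)], tissues=("brain",))
        t2 = make_transcript("b", [(0, 100), (200, 350)], tissues=("liver",))
        catalogue = cluster_genes([t1, t2], "iso")
        matrix = build_detection_matrix(
            catalogue, TISSUES, JunctionSupportTable(), ExpressionTable()
        )
        summary = summarize_tissues(matrix, catalogue)
        assert all(not v for v in summary.tissue_specific_genes.values())

    def test_planted_rescue_set_recovered_exactly(self, bundle):
        truth = bundle.truth.transcripts()
        catalogue = cluster_genes(bundle.transcripts, "iso")
        m = build_detection_matrix(
            catalogue, bundle.config.tissues, bundle.junction_support, bundle.expression
        )
        rescued = {k for k, v in m.status.items() if v is Detection.RESCUED}
        planted = set()
        for row in truth.itertuples():
            for part in str(row.detection).split(";"):
                if part.endswith(":rescued"):
                    planted.add((row.object_id, part.split(":")[0]))
        assert rescued == planted
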