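import pytest

from refinery.pipeline import PipelineConfig, run
from refinery.simulate import SimulationConfig, simulate

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One synthetic bundle shared by the whole session (written to disk)."""
    d = tmp_path_factory.mktemp("bundle")
    b = simulate(SimulationConfig(seed=BUNDLE_SEED), out_dir=str(d))
    b.out_dir = str(d)
    return b


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    return run(PipelineConfig.for_bundle_dir(bundle.out_dir, str(out)))


def make_transcript(tid, pairs, strand="+", chrom="chr1", tissues=(), gene_id=""):
    from refinery.annotation import GenomicInterval, TranscriptModel

    return TranscriptModel(
        tid,
        chrom,
        strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs),
        gene_id,
        frozenset(tissues),
    )
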