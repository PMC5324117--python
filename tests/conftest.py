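from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from lncmap.io import GenomicInterval, TranscriptModel
from lncmap.simulate import SimulationConfig, generate_annotation

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_tx(tid, exons, chrom="chr1", strand="+", gene_id=None, biotype="novel"):
    """Shorthand transcript constructor for fixtures."""
    return TranscriptModel(
        tid,
        gene_id or tid,
        tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons),
        biotype,
    )


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def dataset(default_config):
    """The default synthetic dataset (in memory, seed 42)."""
    annotation, transcripts, sequences, truth = generate_annotation(default_config)
    return SimpleNamespace(
        annotation=annotation,
        transcripts=transcripts,
        sequences=sequences,
        truth=truth,
        config=default_config,
    )


@pytest.fixture(scope="session")
def emitted(tmp_path_factory, default_config):
    """The default dataset written to disk."""
    from lncmap.simulate import emit_dataset

    outdir = tmp_path_factory.mktemp("dataset")
    truth = emit_dataset(default_config, outdir)
    return SimpleNamespace(outdir=outdir, truth=truth, config=default_config)
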