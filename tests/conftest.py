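import numpy as np
import pytest

from lavidascope.pipeline import PipelineConfig, run_discovery
from lavidascope.simulate import SimConfig, make_metagenome


@pytest.fixture
def rng():
    return np.random.default_rng(0)


SMALL_CONFIG = dict(
    seed=11, n_virophages=8, n_decoys=6, n_giant_viruses=2,
    n_accessory_families=2,
)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A small generated corpus with files on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("corpus")
    corpus = make_metagenome(SimConfig(**SMALL_CONFIG), outdir=outdir)
    return corpus, outdir


@pytest.fixture(scope="session")
def pipeline_run(small_corpus, tmp_path_factory):
    """One full discovery run over the small corpus."""
    corpus, indir = small_corpus
    outdir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        contigs=str(indir / "contigs.fasta"),
        annotations=str(indir / "annotations.gff3"),
        proteins=str(indir / "proteins.faa"),
        habitats=str(indir / "habitats.tsv"),
        seeds_dir=str(indir / "seeds"),
        giants=str(indir / "giants.fasta"),
        giants_gff=str(indir / "giants.gff3"),
        outdir=str(outdir),
        seed=0,
    )
    manifest = run_discovery(config)
    return corpus, config, manifest, outdir
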