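import pytest

from plastidtx import fixtures as fx
from plastidtx.model import Gene, GeneModel
from plastidtx.segments import TranscribedSegment
from plastidtx.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def printed_model():
    """Gene model transcribed from the packaged printed gene table."""
    return fx.load_gene_table()


@pytest.fixture(scope="session")
def printed_table():
    return fx.load_ncrna_table()


@pytest.fixture(scope="session")
def printed_catalog():
    return fx.load_ncrna_records()


@pytest.fixture(scope="session")
def exact_bundle():
    """Noise-free synthetic bundle (deterministic expected depth)."""
    return simulate(SimulationConfig(seed=11, depth_model="exact"))


def make_gene(id, start, end, strand, gene_class="protein", exons=()):
    return Gene(id=id, name=id, gene_class=gene_class, strand=strand,
                start=start, end=end, exons=tuple(exons))


def make_model(genes, genome_length=None):
    length = genome_length or max(g.end for g in genes) + 500
    return GeneModel(genes=list(genes), genome_length=length)


def make_segment(start, end, strand, depth=1.0):
    length = end - start + 1
    return TranscribedSegment(start=start, end=end, strand=strand,
                              mean_depth=depth, total_depth=depth * length)


@pytest.fixture
def toy():
    """Expose the small builders to tests as one handle."""
    return {"gene": make_gene, "model": make_model, "segment": make_segment}
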