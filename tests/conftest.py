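import numpy as np
import pytest

from viropan.datamodel import Genome, GenomeSet, ORF, PipelineConfig
from viropan.simulate import make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """The 'small' simulated dataset: 10 genomes, 2 family groups, ~60 root
    families at low divergence, with planted external reference collections."""
    truth, gs, _files = make_fixture("small", seed=1)
    return truth, gs


@pytest.fixture()
def cfg():
    return PipelineConfig()


@pytest.fixture()
def tiny_gs():
    """Two hand-built genomes with five ORFs."""
    seqs = {
        "o1": ("gA", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        "o2": ("gA", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVA"),
        "o3": ("gA", "MNSPWTNTGGAYVQRSTLAPQNMVEIK"),
        "o4": ("gB", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        "o5": ("gB", "MWWSEWLEHHHKQNNPPGG"),
    }
    orfs = {k: ORF(k, g, s) for k, (g, s) in seqs.items()}
    genomes = [
        Genome("gA", "FamX", ["o1", "o2", "o3"]),
        Genome("gB", "FamY", ["o4", "o5"]),
    ]
    return GenomeSet(genomes, orfs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
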