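import numpy as np
import pytest

from tfbsbench import pwm, simulate
from tfbsbench.seqio import Peak


@pytest.fixture(scope="session")
def uniform_chain():
    return simulate.MarkovChain(0, np.full(4, 0.25))


@pytest.fixture(scope="session")
def foxa_motif():
    return simulate.default_foxa_motif()


@pytest.fixture(scope="session")
def sharp_motif():
    """High-information TRTTTRYH-core motif used for recovery checks."""
    return simulate.default_foxa_motif(core_mass=0.97, flank_mass=0.7)


@pytest.fixture(scope="session")
def consensus_motif():
    """Deterministic 8-column motif spelling TGTTTACT."""
    idx = [("ACGT".index(c)) for c in "TGTTTACT"]
    return simulate.GroundTruthMotif(np.eye(4)[idx], core_offset=0,
                                     core_consensus="TGTTTACT")


@pytest.fixture(scope="session")
def random_peaks(uniform_chain):
    """50 random 200-bp background peaks."""
    return simulate.generate_background(uniform_chain, 50, 200, seed=1234)


@pytest.fixture(scope="session")
def training_sites(foxa_motif):
    return simulate.generate_training_sites(foxa_motif, 53, 3, seed=77)


@pytest.fixture(scope="session")
def mono_model(training_sites):
    m = pwm.build_mono_pwm(training_sites)
    m.model_id = "mono_test"
    return m


@pytest.fixture(scope="session")
def di_model(training_sites):
    m = pwm.build_di_pwm(training_sites)
    m.model_id = "di_test"
    return m


@pytest.fixture
def toy_peak():
    return Peak(id="p1", seq="ACGTACGTACGTACGTACGT", height=20.0)
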