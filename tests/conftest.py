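import numpy as np
import pytest

from ssu_census.qc import InternalWindow
from ssu_census.seqio import AlignedSequence
from ssu_census.synthetic import SimulationConfig, generate_dataset


def aseq(seq_id, residues, source="metagenome", environment=""):
    return AlignedSequence(seq_id, residues, source, environment)


@pytest.fixture(scope="session")
def small_dataset():
    """Clean 3-phyla community with all artifact classes planted."""
    cfg = SimulationConfig(
        n_phyla=3, otus_per_phylum=5, seqs_per_otu=4,
        chimera_fraction=0.05, truncated_fraction=0.05, gappy_fraction=0.05,
        rng_seed=42,
    )
    seqs, truth, trees = generate_dataset(cfg)
    return cfg, seqs, truth, trees


@pytest.fixture
def window900():
    return InternalWindow(0, 900)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
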