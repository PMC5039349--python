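import numpy as np
import pytest

from acetopan.io_formats import GenomePanel, ProteinRecord
from acetopan.similarity import FilterThresholds, ScoringScheme
from acetopan.synthetic import (
    SimulationParams,
    generate_panel,
    random_protein,
    uniform_dispensable_spec,
)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def thresholds():
    return FilterThresholds()


@pytest.fixture(scope="session")
def small_panel_truth():
    """Three genomes, zero divergence, no paralogs: trivially recoverable."""
    params = SimulationParams(
        n_genomes=3,
        n_core=6,
        dispensable_spec=((2, 3),),
        n_specific_per_genome=2,
        divergence=0.0,
        paralog_rate=0.0,
        seed=11,
    )
    return generate_panel(params)


@pytest.fixture(scope="session")
def diverged_panel_truth():
    """Five genomes at 5% divergence, under 50 proteins, for oracle checks."""
    params = SimulationParams(
        n_genomes=5,
        n_core=5,
        dispensable_spec=((2, 2), (3, 1)),
        n_specific_per_genome=1,
        divergence=0.05,
        paralog_rate=0.0,
        seed=7,
    )
    return generate_panel(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)


def make_panel(seqs_by_genome: dict[str, dict[str, str]]) -> GenomePanel:
    """Build a panel from {genome: {protein_id: sequence}} literals."""
    genomes = list(seqs_by_genome)
    proteins = [
        ProteinRecord(pid, gid, seq)
        for gid, prots in seqs_by_genome.items()
        for pid, seq in prots.items()
    ]
    return GenomePanel(genomes=genomes, proteins=proteins)
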