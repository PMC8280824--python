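import numpy as np
import pandas as pd
import pytest

import minorlens as ml


@pytest.fixture(scope="session")
def sim_config():
    return ml.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def toy_dataset(sim_config):
    """Toy genome + annotation + truth table, simulated once per session."""
    genome, transcripts, truth = ml.simulate_genome(sim_config)
    return genome, transcripts, truth


@pytest.fixture(scope="session")
def toy_introns(toy_dataset):
    genome, transcripts, _ = toy_dataset
    return ml.extract_introns(transcripts, genome)


@pytest.fixture(scope="session")
def toy_classification(toy_introns):
    return ml.classify_catalog(toy_introns)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_genome(tmp_path):
    """Hand-written two-contig FASTA for parsing tests."""
    path = tmp_path / "genome.fa"
    path.write_text(">chr1\nACGT\n>chr2\nAACCGGTTAACC\n")
    return str(path)


def make_gtf(tmp_path, lines, name="anno.gtf"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return str(path)
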