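import numpy as np
import pytest

from trimscope import Read, RunConfig, SimulationConfig, generate_genome, simulate_reads


def make_read(qualities, sequence=None, rid="r0", mate=None):
    qualities = list(qualities)
    if sequence is None:
        sequence = "A" * len(qualities)
    return Read(rid, sequence, qualities, mate)


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-scale simulation: 12 genes, 4000 read pairs."""
    return SimulationConfig(
        seed=7,
        n_genes=12,
        genome_length=120_000,
        transcript_length=(500, 2000),
        n_read_pairs=4000,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate_reads(generate_genome(tiny_config))


@pytest.fixture(scope="session")
def tiny_run_config(tiny_config):
    return RunConfig(sim=tiny_config)
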