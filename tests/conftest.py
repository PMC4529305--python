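import pytest
from hypothesis import HealthCheck, settings

from potoroo import synthetic as syn

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_cfg():
    return syn.SimConfig(n_genes=10, seed=42)


@pytest.fixture(scope="session")
def sim_world(sim_cfg):
    """(genome, genes, isoforms) for a small fixed-seed universe."""
    genome, genes = syn.generate_genome(sim_cfg)
    isoforms = syn.generate_transcriptome(genes, genome, sim_cfg)
    return genome, genes, isoforms


@pytest.fixture(scope="session")
def sim_reads(sim_world, sim_cfg):
    return syn.simulate_reads(sim_world[2], sim_cfg, 2000)


@pytest.fixture(scope="session")
def sim_reads_clean(sim_world, sim_cfg):
    return syn.simulate_reads(sim_world[2], sim_cfg, 500, error_free=True)
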