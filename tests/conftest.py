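import pytest

from spermchrom import simulate as sim
from spermchrom.config import SimConfig, RegionSpec, HET_MIX


@pytest.fixture(scope="session")
def tiny_config():
    """Small single-chromosome population used across the unit suite."""
    return SimConfig(seed=11, n_chromosomes=1, chrom_length_bp=50_000,
                     n_cells=60, depth=20.0)


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return sim.generate_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_population(tiny_config, tiny_genome):
    return sim.simulate_population(tiny_config, tiny_genome)


@pytest.fixture(scope="session")
def tiny_fragments(tiny_config, tiny_population):
    return sim.simulate_mnase_fragments(tiny_config, tiny_population)


def uniform_config(mix=HET_MIX, hmd_k4=0.0, hmd_k27=0.0, **kwargs):
    """Config whose whole genome is one region per chromosome."""
    defaults = dict(seed=7, n_chromosomes=1, chrom_length_bp=50_000,
                    n_cells=100, depth=25.0)
    defaults.update(kwargs)
    cfg = SimConfig(**defaults)
    cfg.region_specs = [
        RegionSpec(cfg.chrom_name(i), 0, cfg.chrom_length_bp, mix,
                   hmd_k4, hmd_k27, "intergenic")
        for i in range(cfg.n_chromosomes)
    ]
    return cfg
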