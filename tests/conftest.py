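import random

import pytest

from panmem.engine import PangenomeIndex
from panmem.simulate import SimConfig, simulate_pangenome, simulate_reads


def random_dna(rng: random.Random, n: int, alphabet: bytes = b"ACGT") -> bytes:
    return bytes(rng.choice(alphabet) for _ in range(n))


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(ref_length=20000, n_haplotypes=6, snp_rate=0.001,
                    indel_rate=0.0001, read_length=100, n_pairs=150,
                    insert_mean=300.0, insert_sd=25.0,
                    subst_error_rate=0.002, seed=7)
    return cfg, simulate_pangenome(cfg)


@pytest.fixture(scope="session")
def small_index(small_sim):
    _, sim = small_sim
    return PangenomeIndex.build_from_vcf(sim.reference, sim.variants,
                                         sim.sample_names)


@pytest.fixture(scope="session")
def small_reads(small_sim):
    cfg, sim = small_sim
    return simulate_reads(sim.haplotypes, sim.lift_maps, cfg)
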