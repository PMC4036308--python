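import numpy as np
import pytest

from lactpath.io import Dataset
from lactpath.lmm import TraitParams
from lactpath.simulate import SimulationConfig, simulate_dataset


def as_dataset(sim) -> Dataset:
    """Wrap an in-memory simulated dataset for the pipeline helpers."""
    return Dataset(
        genes=sim.genes,
        pathways=sim.pathways,
        snps=sim.snps,
        genotypes=sim.genotypes,
        pedigree=sim.pedigree,
        phenotypes=sim.phenotypes,
    )


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A few hundred animals / one-thousand SNPs: fast unit-test scale."""
    return SimulationConfig(
        seed=11,
        n_chromosomes=3,
        chrom_length_bp=10_000_000,
        n_snps=1_000,
        n_genes=200,
        pathway_sizes=(12,),
        n_founders=80,
        n_generations=2,
        n_animals=300,
        traits=(TraitParams("milk", h2=0.33, r2=0.56),),
        n_causal=20,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim) -> Dataset:
    return as_dataset(tiny_sim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
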