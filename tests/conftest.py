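import numpy as np
import pytest

from kinlr.ancestry import EMSettings
from kinlr.genotype_io import GenotypeTable
from kinlr.pipeline import ExperimentConfig
from kinlr.synthetic_data import SyntheticConfig, generate_dataset


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A desk-scale four-population study design for pipeline tests."""
    params = dict(
        n_populations=4,
        n_individuals_per_pop=(20, 25, 20, 15),
        n_loci_total=60,
        n_forensic_loci=13,
        alleles_per_locus=(4, 10),
        drift_F=0.15,
        admixture_alpha=0.1,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def small_experiment(seed: int = 11, **overrides) -> ExperimentConfig:
    return ExperimentConfig(
        synthetic=small_config(seed=seed),
        em=EMSettings(K=4, n_replicates=3, max_iterations=300, seed=seed + 1),
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One shared small synthetic dataset with ground truth."""
    return generate_dataset(small_config())


@pytest.fixture()
def tiny_table() -> GenotypeTable:
    """Four individuals, three loci, one forensic locus, one missing genotype."""
    genotypes = np.array(
        [
            [[10, 12], [7, 7], [9, 11]],
            [[10, 10], [7, 8], [9, 9]],
            [[12, 14], [8, 8], [-9, -9]],
            [[10, 14], [7, 8], [11, 11]],
        ]
    )
    return GenotypeTable(
        individuals=["i1", "i2", "i3", "i4"],
        populations=["p1", "p1", "p2", "p2"],
        loci=["CODIS01", "STR001", "STR002"],
        forensic=np.array([True, False, False]),
        genotypes=genotypes,
    )
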