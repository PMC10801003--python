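import numpy as np
import pandas as pd
import pytest

from pleionet.datatypes import GenotypeMatrix, SimConfig
from pleionet.simulate import random_architecture, simulate_genotypes, simulate_phenotypes


def make_geno(dosage, positions=None, chrom="Chr1", samples=None) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    markers = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "id": [f"{chrom}_{p}" for p in positions],
        "ref": "A", "alt": "T",
    })
    samples = samples or [f"S{i}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, markers=markers, samples=samples)


@pytest.fixture(scope="session")
def sim_panel():
    """A small simulated panel with LD, reused across tests."""
    geno = simulate_genotypes(SimConfig(
        n_samples=200, n_markers=600,
        chrom_lengths=(("Chr1", 20_000_000), ("Chr2", 20_000_000)),
        seed=11))
    return geno


@pytest.fixture(scope="session")
def sim_pheno(sim_panel):
    arch = random_architecture(sim_panel, seed=12, n_env=2, n_rep=2)
    pheno, truth = simulate_phenotypes(sim_panel, arch, seed=13)
    return pheno, truth, arch
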