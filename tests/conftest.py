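import numpy as np
import pandas as pd
import pytest

from cogsys.genotypes import GenotypeMatrix
from cogsys.sim import SimConfig, simulate_cohort


def make_genotypes(dosages, chrom=None, pos=None, individuals=None):
    """Small helper to build a GenotypeMatrix from a raw dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = chrom if chrom is not None else ["chr1"] * m
    pos = pos if pos is not None else list(range(1000, 1000 + m * 100, 100))
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(dosages, snps, individuals)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort with planted signal, shared across tests."""
    cfg = SimConfig(
        n_individuals=300, n_snps=600, n_chromosomes=4, n_genes=120,
        n_pathways=10, pathway_size_range=(10, 30), causal_gene_count=8,
        causal_effect_total=0.15, seed=11,
    )
    return cfg, simulate_cohort(cfg)
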