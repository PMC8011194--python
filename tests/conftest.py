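import numpy as np
import pytest

from sgsd import DemeSimulationParams, GenotypeTable, simulate_demes
from sgsd.genotype_io import MISSING


def make_table(genotypes, x=None, y=None, groups=None, loci=None,
               coord_system="planar"):
    """Build a GenotypeTable from a nested list [(a1, a2) per locus] per sample."""
    geno = np.array(genotypes, dtype=np.int64)
    n = geno.shape[0]
    return GenotypeTable(
        sample_ids=[f"s{i}" for i in range(n)],
        x=np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float),
        y=np.zeros(n) if y is None else np.asarray(y, dtype=float),
        groups=np.array(groups if groups is not None else [None] * n, dtype=object),
        loci=loci if loci is not None else [f"L{l+1}" for l in range(geno.shape[1])],
        genotypes=geno,
        coord_system=coord_system,
    )


def to_pylists(table):
    """Genotypes as nested python lists of int tuples (for the loop oracles)."""
    return [
        [tuple(int(v) for v in table.genotypes[i, l]) for l in range(table.n_loci)]
        for i in range(table.n_samples)
    ]


@pytest.fixture
def tiny_table():
    # 3 samples, 2 loci; one missing genotype
    return make_table(
        [
            [(101, 103), (140, 140)],
            [(101, 101), (142, 144)],
            [(103, 105), (MISSING, MISSING)],
        ],
        x=[0.0, 3.0, 10.0],
        y=[0.0, 4.0, 0.0],
        groups=["g1", "g1", "g2"],
    )


@pytest.fixture(scope="session")
def demes_table():
    """Two well-differentiated demes with some missing data (shared fixture)."""
    from sgsd import inject_missingness

    t = simulate_demes(
        DemeSimulationParams(K=2, F=0.25, samples_per_deme=40, loci=8,
                             ancestral_alleles=5, seed=11)
    )
    return inject_missingness(t, 0.05, seed=12)


@pytest.fixture(scope="session")
def hwe_table():
    """Single panmictic deme (HWE null)."""
    return simulate_demes(
        DemeSimulationParams(K=1, F=0.2, samples_per_deme=100, loci=10,
                             ancestral_alleles=6, seed=21)
    )
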