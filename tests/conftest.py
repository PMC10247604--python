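import numpy as np
import pytest

from hapsparse import (
    GenotypeMatrix,
    SimConfig,
    het_to_missing,
    qc_filter,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_pop():
    """A 100-line, 2-chromosome RIL population with 3 environments."""
    cfg = SimConfig(
        n_lines=100, n_chrom=2, snps_per_chrom=40, n_envs=3, n_reps=2, seed=11
    )
    g, plots, truth_blues, truth = simulate_population(cfg)
    return {"cfg": cfg, "g": g, "plots": plots, "truth_blues": truth_blues, "truth": truth}


@pytest.fixture(scope="session")
def qc_geno(small_pop):
    g, _ = qc_filter(het_to_missing(small_pop["g"]))
    return g


def make_genotypes(dosage, pos=None, chrom=None, line_prefix="L", snp_prefix="s"):
    """Small helper to build a GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if chrom is None:
        chrom = ["1"] * m
    return GenotypeMatrix(
        line_ids=[f"{line_prefix}{i}" for i in range(n)],
        snp_ids=[f"{snp_prefix}{j}" for j in range(m)],
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos),
        dosage=dosage,
    )
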