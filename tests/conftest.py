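import numpy as np
import pandas as pd
import pytest

from pathpgs import GenotypeMatrix, SimConfig, SumStats, simulate_study

_NONPAL = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def random_genotypes(rng, n, m, chrom="1", bp_start=1000, bp_step=500,
                     missing_rate=0.0):
    """Small i.i.d.-dosage genotype matrix for unit tests."""
    mafs = rng.uniform(0.1, 0.5, size=m)
    dos = rng.binomial(2, mafs, size=(n, m)).astype(float)
    if missing_rate:
        dos[rng.random((n, m)) < missing_rate] = np.nan
    pairs = [_NONPAL[i % len(_NONPAL)] for i in range(m)]
    snps = pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(m)],
            "chrom": chrom,
            "bp": bp_start + bp_step * np.arange(m),
            "a1": [p[0] for p in pairs],
            "a2": [p[1] for p in pairs],
        }
    )
    return GenotypeMatrix(
        individuals=[f"i{i}" for i in range(n)], snps=snps, dosages=dos
    )


def sumstats_for(genos, rng, betas=None):
    """Summary statistics aligned with a genotype matrix's alleles."""
    m = len(genos.snps)
    t = genos.snps[["id", "chrom", "bp", "a1", "a2"]].copy()
    t["beta"] = rng.normal(0, 0.1, m) if betas is None else np.asarray(betas, float)
    t["se"] = rng.uniform(0.01, 0.05, m)
    t["p"] = rng.uniform(1e-10, 1, m)
    return SumStats(t)


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused by integration-level tests."""
    cfg = SimConfig(
        n_individuals=500, n_genes=30, genes_per_chrom=10,
        snps_per_gene=10, n_pathway_genes=5, seed=11,
    )
    return simulate_study(cfg)
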