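import numpy as np
import pandas as pd
import pytest

from aiqtl import SimConfig
from aiqtl.simulate import simulate_genotypes, simulate_negbin_sbb


def sbb_counts(rng, n, alpha, mean=30.0, size=100.0):
    """Draw (a, total) pairs from NegBin total + symmetric beta-binomial split."""
    total = rng.negative_binomial(size, size / (size + mean), n)
    total = np.maximum(total, 2)
    p = rng.beta(alpha, alpha, n)
    a = rng.binomial(total, p)
    return a.astype(np.int64), total.astype(np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def cis_strong_groups():
    """(hom, het) count arrays with a strong genotype effect on imbalance."""
    rng = np.random.default_rng(41)
    hom = sbb_counts(rng, 300, alpha=100.0)
    het = sbb_counts(rng, 200, alpha=5.0)
    return hom, het


@pytest.fixture
def null_groups():
    """(hom, het) count arrays drawn from the identical distribution."""
    rng = np.random.default_rng(42)
    hom = sbb_counts(rng, 300, alpha=50.0)
    het = sbb_counts(rng, 200, alpha=50.0)
    return hom, het


def make_scan_dataset(
    n_genes=20,
    n_cis=5,
    n_samples=150,
    alpha_het_cis=5.0,
    maf=0.3,
    seed=7,
):
    """Multi-gene counts/genotypes/pairs tables with known cis genes.

    Genes g000..g{n_cis-1} carry a true effect at their paired variant;
    the rest are null.  Returns (counts, genotypes, pairs, cis_genes).
    """
    rng = np.random.default_rng(seed)
    counts_rows, geno_rows, pair_rows = [], [], []
    cis_genes = set()
    for gi in range(n_genes):
        gene = f"g{gi:03d}"
        variant = f"v{gi:03d}"
        is_cis = gi < n_cis
        if is_cis:
            cis_genes.add(gene)
        genotypes = simulate_genotypes(n_samples, maf, rng)
        cfg = SimConfig(
            n_individuals=n_samples,
            maf=maf,
            alpha_het=alpha_het_cis if is_cis else 100.0,
            seed=0,
        )
        rep = simulate_negbin_sbb(genotypes, cfg, rng)
        for o in rep.observations:
            counts_rows.append(
                dict(
                    sample_id=o.sample_id,
                    gene_id=gene,
                    a_count=o.a_count,
                    total_count=o.total_count,
                )
            )
        for g in rep.genotypes:
            geno_rows.append(
                dict(sample_id=g.sample_id, variant_id=variant, cls=g.cls.value)
            )
        pair_rows.append(
            dict(
                variant_id=variant,
                gene_id=gene,
                tss_distance=int(rng.integers(-500_000, 500_000)),
                maf=maf,
                eqtl_log10_p=float(-rng.uniform(5, 30)),
                n_informative_samples=n_samples,
                median_reads=30.0,
            )
        )
    return (
        pd.DataFrame(counts_rows),
        pd.DataFrame(geno_rows),
        pd.DataFrame(pair_rows),
        cis_genes,
    )
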