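import numpy as np
import pytest

from sasbx.divergence import gene_divergence_table, snp_divergence_table
from sasbx.expression import delta_table
from sasbx.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic study reused across modules (kept cheap)."""
    return simulate_study(SimConfig(n_genes=300, snps_per_gene=3, N_m=5000,
                                    N_f=5000, n_populations=6, seed=42))


@pytest.fixture(scope="session")
def merged_small(small_study):
    """Gene x population divergence merged with Δ for the small study."""
    gene = gene_divergence_table(snp_divergence_table(small_study.counts))
    deltas = delta_table(small_study.expression, small_study.samples)
    merged = gene.merge(deltas[["gene_id", "delta"]], on="gene_id", how="inner")
    return merged.dropna(subset=["delta", "mean_fst"]).reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
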