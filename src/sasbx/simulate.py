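"""Synthetic genotype-count and expression data with known ground truth.

The generator realises the equilibrium sexually-antagonistic model: each
gene gets an expression bias Δ, an SA potential A(Δ) = A_max·(1 - Δ²)
(smoothly vanishing at complete bias, where one sex is silent and at
equilibrium neither sex is under selection), and the implied additive
effect s_m = 2·√A·Δ, so the per-SNP prediction F_ST = 4·p·q·A·Δ² holds
exactly by construction (p·q·s_m² = 4·p·q·A·Δ²).  Zygote minor-allele
frequencies are drawn from the fitted MAF density; one generation of
sex-specific viability selection shifts adult frequencies to p ± p·q·s_m,
from which male and female allele samples are drawn binomially per
population.  Expression data are per-sample log-normal abundances around
sex means m = total·(1+Δ)/2 and f = total·(1-Δ)/2, for 14 male and 6
female samples by default.

All randomness flows from a single seed through named substreams, so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import delta_statistic
from .inference import PriorSpec

_SUBSTREAMS = {"delta": 1, "maf": 2, "counts": 3, "expression": 4, "totals": 5}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[name],)))


@dataclass
class SimConfig:
    """Study-level configuration; defaults are the reference conditions.

    26 populations mirror the genotype panel structure, 14 male / 6 female
    expression samples mirror the expression atlas; A_max = 0.04 puts peak
    additive effects near s ≈ 0.2·Δ, and 2·10⁴ alleles per sex gives a
    per-SNP sampling baseline F_ST of 2.5·10⁻⁵.
    """

    n_genes: int = 3000
    snps_per_gene: int = 5
    N_m: int = 20000
    N_f: int = 20000
    n_populations: int = 26
    delta_distribution: str = "uniform"  # uniform on [-1, 1]
    A_max: float = 0.04
    maf: str = "fitted"  # "fitted", "uniform", or a fixed float
    expression_total_log_mean: float = float(np.log(100.0))
    expression_total_log_sd: float = 1.0
    expression_noise_cv: float = 0.2
    n_male_samples: int = 14
    n_female_samples: int = 6
    single_target_snp: bool = False  # only one SNP per gene carries s_m
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "snps_per_gene", "N_m", "N_f", "n_populations",
                     "n_male_samples", "n_female_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.A_max < 0:
            raise ValueError("A_max must be non-negative")


@dataclass
class GroundTruth:
    """Per-gene and per-SNP generative parameters."""

    genes: pd.DataFrame  # gene_id, delta_true, A_true, s_m_true
    snps: pd.DataFrame   # snp_id, gene_id, p_true, s_m_snp


@dataclass
class SimulatedStudy:
    config: SimConfig
    counts: pd.DataFrame
    expression: pd.DataFrame
    samples: pd.DataFrame
    genes_bed: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.10g")
        self.counts.to_csv(out / "counts.tsv", **kw)
        self.expression.to_csv(out / "expression.tsv", **kw)
        self.samples.to_csv(out / "samples.tsv", **kw)
        self.genes_bed.to_csv(out / "genes.bed", sep="\t", index=False, header=False)
        truth = self.truth.snps.merge(self.truth.genes, on="gene_id")
        truth.to_csv(out / "truth.tsv", **kw)


def simulate_locus_counts(p, s_m, N_m: int, N_f: int, rng: np.random.Generator):
    """Sample adult male/female allele counts at loci with effect s_m.

    Adult frequencies are p + p·q·s_m in males and p - p·q·s_m in females
    (the s_f = -s_m equilibrium); counts are binomial draws.
    """
    p = np.asarray(p, dtype=float)
    s_m = np.asarray(s_m, dtype=float)
    pq = p * (1.0 - p)
    pm = p + pq * s_m
    pf = p - pq * s_m
    if np.any((pm < 0) | (pm > 1) | (pf < 0) | (pf > 1)):
        raise ValueError("adult frequency outside [0, 1]; reduce |s_m|")
    return rng.binomial(N_m, pm), rng.binomial(N_f, pf)


def simulate_expression(delta_true: float, total: float, cv: float,
                        n_m_samples: int, n_f_samples: int,
                        rng: np.random.Generator):
    """Per-sample abundances around sex means set by Δ and the total.

    m = total·(1+Δ)/2, f = total·(1-Δ)/2; samples are log-normal with the
    requested coefficient of variation (a silent sex yields exact zeros,
    so Δ = ±1 is recovered exactly).
    """
    if not -1.0 <= delta_true <= 1.0:
        raise ValueError("delta_true must lie in [-1, 1]")
    if total <= 0:
        raise ValueError("total expression must be positive")
    m = total * (1.0 + delta_true) / 2.0
    f = total * (1.0 - delta_true) / 2.0

    def _samples(mean, n):
        if mean == 0.0:
            return np.zeros(n)
        if cv == 0.0:
            return np.full(n, mean)
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)

    return _samples(m, n_m_samples), _samples(f, n_f_samples)


def _draw_maf(config: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if config.maf == "fitted":
        return PriorSpec().sample(rng, size)
    if config.maf == "uniform":
        return rng.uniform(0.05, 0.5, size)
    return np.full(size, float(config.maf))


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate the full synthetic study: counts, expression, ground truth.

    Each gene draws Δ, sets A = A_max·(1 - Δ²) and s_m = 2·√A·Δ; each of
    its SNPs draws a zygote MAF shared across populations, and every
    population contributes an independent binomial sample of adult male
    and female alleles.
    """
    cfg = config
    rng_delta = substream(cfg.seed, "delta")
    rng_maf = substream(cfg.seed, "maf")
    rng_counts = substream(cfg.seed, "counts")
    rng_expr = substream(cfg.seed, "expression")
    rng_tot = substream(cfg.seed, "totals")

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    delta_true = rng_delta.uniform(-1.0, 1.0, cfg.n_genes)
    A_true = cfg.A_max * (1.0 - delta_true**2)
    s_m_true = 2.0 * np.sqrt(A_true) * delta_true

    n_snps = cfg.n_genes * cfg.snps_per_gene
    p_true = _draw_maf(cfg, rng_maf, n_snps)
    snp_gene = np.repeat(np.arange(cfg.n_genes), cfg.snps_per_gene)
    snp_ids = [f"{gene_ids[g]}_s{j}" for g, j in
               zip(snp_gene, np.tile(np.arange(cfg.snps_per_gene), cfg.n_genes))]
    s_snp = s_m_true[snp_gene].copy()
    if cfg.single_target_snp:
        target = np.arange(cfg.n_genes) * cfg.snps_per_gene  # first SNP per gene
        mask = np.zeros(n_snps, dtype=bool)
        mask[target] = True
        s_snp[~mask] = 0.0

    pops = [f"P{k:02d}" for k in range(cfg.n_populations)]
    frames = []
    for pop in pops:
        n_m, n_f = simulate_locus_counts(p_true, s_snp, cfg.N_m, cfg.N_f, rng_counts)
        frames.append(pd.DataFrame({
            "population": pop,
            "gene_id": np.asarray(gene_ids)[snp_gene],
            "snp_id": snp_ids,
            "chrom": "chr1",
            "pos": 1 + snp_gene * 1000 + np.tile(np.arange(cfg.snps_per_gene), cfg.n_genes) * 100,
            "allele": "A",
            "n_m": n_m, "N_m": cfg.N_m, "n_f": n_f, "N_f": cfg.N_f,
        }))
    counts = pd.concat(frames, ignore_index=True)

    totals = rng_tot.lognormal(cfg.expression_total_log_mean,
                               cfg.expression_total_log_sd, cfg.n_genes)
    male_cols = [f"M{i:02d}" for i in range(cfg.n_male_samples)]
    female_cols = [f"F{i:02d}" for i in range(cfg.n_female_samples)]
    expr_rows = np.empty((cfg.n_genes, cfg.n_male_samples + cfg.n_female_samples))
    for i in range(cfg.n_genes):
        mv, fv = simulate_expression(delta_true[i], totals[i], cfg.expression_noise_cv,
                                     cfg.n_male_samples, cfg.n_female_samples, rng_expr)
        expr_rows[i, :cfg.n_male_samples] = mv
        expr_rows[i, cfg.n_male_samples:] = fv
    expression = pd.DataFrame(expr_rows, columns=male_cols + female_cols)
    expression.insert(0, "gene_id", gene_ids)

    samples = pd.DataFrame({
        "sample_id": male_cols + female_cols,
        "sex": ["M"] * cfg.n_male_samples + ["F"] * cfg.n_female_samples,
        "tissue": ["testis"] * cfg.n_male_samples + ["ovary"] * cfg.n_female_samples,
    })

    genes_bed = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(cfg.n_genes) * 1000,  # 0-based half-open
        "end": np.arange(cfg.n_genes) * 1000 + 1000,
        "gene_id": gene_ids,
    })

    truth = GroundTruth(
        genes=pd.DataFrame({"gene_id": gene_ids, "delta_true": delta_true,
                            "A_true": A_true, "s_m_true": s_m_true}),
        snps=pd.DataFrame({"snp_id": snp_ids, "gene_id": np.asarray(gene_ids)[snp_gene],
                           "p_true": p_true, "s_m_snp": s_snp}),
    )
    return SimulatedStudy(config=cfg, counts=counts, expression=expression,
                          samples=samples, genes_bed=genes_bed, truth=truth)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
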