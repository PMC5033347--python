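"""Per-SNP male-vs-female tests, FDR control and the detection power analysis.

Each SNP yields a 2x2 allele-count table (sex x allele); the null of equal
male and female frequencies is tested either by the exact conditional
(Fisher) test or by the Pearson chi-square without continuity correction.
p-values are adjusted by Benjamini-Hochberg, and can be combined across
populations with Fisher's method.  The power analysis asks how often a
genome scan at a given FDR level finds *no* significant SNP, as a function
of the sexually-antagonistic selection coefficient s: zygote MAFs are
drawn from a source density, adult frequencies set to p ± p·q·s, counts
drawn binomially, and the whole testing pipeline re-run per simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .inference import PriorSpec


def persnp_test(n_m, N_m, n_f, N_f, method: str = "exact"):
    """Two-sided test of equal allele frequencies in males vs females.

    ``method="exact"`` uses the conditional exact test (safest at low
    minor-allele frequency); ``"chisq"`` the Pearson chi-square without
    continuity correction (fast, vectorisable).  Empty margins
    (monomorphic tables or zero totals) return p = 1.
    """
    if method == "exact":
        table = np.array([[n_m, N_m - n_m], [n_f, N_f - n_f]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            return 1.0
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "chisq":
        return float(chisq_pvalues(np.atleast_1d(n_m), np.atleast_1d(N_m),
                                   np.atleast_1d(n_f), np.atleast_1d(N_f))[0])
    raise ValueError("method must be 'exact' or 'chisq'")


def chisq_pvalues(n_m, N_m, n_f, N_f):
    """Vectorised Pearson chi-square p-values (df=1, no correction).

    Algebraically identical to the 2x2 contingency chi-square:
    X² = (p̂_m - p̂_f)² / [p̂·q̂·(1/N_m + 1/N_f)] with p̂ the pooled
    frequency.  Monomorphic tables get p = 1.
    """
    n_m = np.asarray(n_m, dtype=float)
    N_m = np.asarray(N_m, dtype=float)
    n_f = np.asarray(n_f, dtype=float)
    N_f = np.asarray(N_f, dtype=float)
    pool = (n_m + n_f) / (N_m + N_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = pool * (1.0 - pool) * (1.0 / N_m + 1.0 / N_f)
        x2 = np.where(var > 0, (n_m / N_m - n_f / N_f) ** 2 / np.where(var > 0, var, 1), 0.0)
    p = stats.chi2.sf(x2, 1)
    return np.where(var > 0, p, 1.0)


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted values (monotone, order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(p_values) -> float:
    """Fisher's method across populations: X² = -2·Σ ln p_i ~ χ²(2k).

    Zero p-values are clamped to the machine minimum with a warning-free
    floor (resampling can legitimately produce 0 without a continuity
    correction upstream).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, 2 * p.size))


@dataclass
class PowerConfig:
    """Configuration of the no-significant-SNP power simulation."""

    n_snps: int
    N_m: int
    N_f: int
    s: float
    maf_source: object = field(default_factory=PriorSpec)  # PriorSpec, float, or (lo, hi)
    fdr_level: float = 0.05
    n_sims: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.n_snps, self.N_m, self.N_f) <= 0:
            raise ValueError("counts must be positive")
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must be in (0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


def _draw_maf(source, rng, size):
    if isinstance(source, PriorSpec):
        return source.sample(rng, size)
    if isinstance(source, (tuple, list)) and len(source) == 2:
        return rng.uniform(source[0], source[1], size)
    return np.full(size, float(source))


def power_none_significant(config: PowerConfig):
    """Monte-Carlo probability that a scan finds zero significant SNPs.

    Per simulation: draw each SNP's zygote MAF, set adult frequencies to
    p ± p·q·s, sample male/female allele counts binomially, compute
    chi-square p-values, apply BH at ``fdr_level`` and record whether no
    SNP is discovered.  Returns ``(probability, standard_error)``.
    """
    rng = np.random.default_rng(config.seed)
    none = 0
    for _ in range(config.n_sims):
        p = _draw_maf(config.maf_source, rng, config.n_snps)
        shift = p * (1.0 - p) * config.s
        pm = np.clip(p + shift, 0.0, 1.0)
        pf = np.clip(p - shift, 0.0, 1.0)
        n_m = rng.binomial(config.N_m, pm)
        n_f = rng.binomial(config.N_f, pf)
        pvals = chisq_pvalues(n_m, np.full(config.n_snps, config.N_m),
                              n_f, np.full(config.n_snps, config.N_f))
        q = bh_fdr(pvals)
        if not np.any(q <= config.fdr_level):
            none += 1
    prob = none / config.n_sims
    se = float(np.sqrt(prob * (1.0 - prob) / config.n_sims))
    return prob, se


def power_curve(s_values, n_snps, N_m, N_f, maf_source=None,
                fdr_level: float = 0.05, n_sims: int = 200, seed: int = 0) -> pd.DataFrame:
    """Probability of zero discoveries as a function of s (shared seed)."""
    rows = []
    for s in s_values:
        cfg = PowerConfig(n_snps=n_snps, N_m=N_m, N_f=N_f, s=float(s),
                          maf_source=maf_source if maf_source is not None else PriorSpec(),
                          fdr_level=fdr_level, n_sims=n_sims, seed=seed)
        prob, se = power_none_significant(cfg)
        rows.append({"s": float(s), "prob_none_significant": prob, "mc_se": se})
    return pd.DataFrame(rows)
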