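"""Per-SNP and per-gene between-sex allele-frequency divergence.

Autosomal allele frequencies are equal in the two sexes at conception.
Sex-differential viability selection makes them diverge within a single
generation; the divergence at a biallelic SNP is quantified as

    F_ST = (p_m - p_f)^2 / (4 p q)

where ``p_m`` and ``p_f`` are the frequencies of the designated allele in
adult males and females, ``p`` the zygote frequency and ``q = 1 - p``.
The zygote frequency is unobservable and is estimated as the unweighted
mean (p_m + p_f)/2 -- the sexes are equally frequent at conception, and
this convention bounds F_ST by 1.

The net-divergence alternative D_a specialises to (p_m - p_f)^2 for a
single biallelic site.  Per-gene summaries average (or take the median or
maximum of) the per-SNP values over the SNPs assigned to the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["n_m", "N_m", "n_f", "N_f"]


@dataclass
class SexCounts:
    """Male/female allele counts at one SNP in one population."""

    snp_id: str
    gene_id: str
    population: str
    n_m: int
    N_m: int
    n_f: int
    N_f: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_m <= self.N_m and 0 <= self.n_f <= self.N_f):
            raise ValueError(f"invalid allele counts for {self.snp_id}")


@dataclass
class SexFreqs:
    """Adult male/female and zygote frequencies of the designated allele."""

    p_m: float
    p_f: float
    p: float
    q: float


def compute_sex_freqs(n_m, N_m, n_f, N_f):
    """Estimate adult and zygote allele frequencies from sex-specific counts.

    Accepts scalars or arrays.  Returns ``(p_m, p_f, p, q)``.  A SNP with
    zero sampled alleles in either sex is an insufficient-data case and all
    four entries are NaN (a missing marker, skipped downstream -- never a
    zero).
    """
    n_m = np.asarray(n_m, dtype=float)
    N_m = np.asarray(N_m, dtype=float)
    n_f = np.asarray(n_f, dtype=float)
    N_f = np.asarray(N_f, dtype=float)
    ok = (N_m > 0) & (N_f > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_m = np.where(ok, n_m / np.where(N_m > 0, N_m, 1), np.nan)
        p_f = np.where(ok, n_f / np.where(N_f > 0, N_f, 1), np.nan)
    p = (p_m + p_f) / 2.0
    return p_m, p_f, p, 1.0 - p


def sex_fst_snp(p_m, p_f, p=None):
    """Between-sex F_ST = (p_m - p_f)^2 / (4 p q) at a single SNP.

    ``p`` defaults to the unweighted mean of the sex-specific frequencies.
    Monomorphic sites (p in {0, 1}) return NaN: the statistic is undefined
    there.  Symmetric under swapping sexes and under allele relabelling.
    """
    p_m = np.asarray(p_m, dtype=float)
    p_f = np.asarray(p_f, dtype=float)
    p = (p_m + p_f) / 2.0 if p is None else np.asarray(p, dtype=float)
    q = 1.0 - p
    denom = 4.0 * p * q
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom > 0, (p_m - p_f) ** 2 / np.where(denom > 0, denom, 1), np.nan)
    return fst[()] if fst.ndim == 0 else fst


def sex_da_snp(p_m, p_f):
    """Net between-sex divergence D_a = (p_m - p_f)^2 for a biallelic site."""
    p_m = np.asarray(p_m, dtype=float)
    p_f = np.asarray(p_f, dtype=float)
    da = (p_m - p_f) ** 2
    return da[()] if da.ndim == 0 else da


def heterozygosity_scaled_fst(fst, p, denominator: str = "pq"):
    """Divide F_ST by heterozygosity (``pq`` or ``2pq``) at the SNP.

    Controls for the proportionality of selection response to
    heterozygosity when regressing divergence on expression bias.
    """
    if denominator not in ("pq", "2pq"):
        raise ValueError("denominator must be 'pq' or '2pq'")
    fst = np.asarray(fst, dtype=float)
    p = np.asarray(p, dtype=float)
    d = p * (1.0 - p)
    if denominator == "2pq":
        d = 2.0 * d
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(d > 0, fst / np.where(d > 0, d, 1), np.nan)
    return out[()] if out.ndim == 0 else out


def aggregate_gene(snp_values, method: str = "mean") -> float:
    """Summarise per-SNP values for one gene (mean, median or max).

    Missing markers (NaN) are excluded first; a gene with nothing left is
    dropped (NaN returned) with a logged warning.
    """
    if method not in ("mean", "median", "max"):
        raise ValueError(f"unknown aggregation method {method!r}")
    vals = np.asarray(list(snp_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        logger.warning("gene dropped: no informative SNPs after exclusions")
        return float("nan")
    return float(getattr(np, method)(vals))


def gene_pi(n_m, N_m, n_f, N_f) -> float:
    """Nucleotide-diversity proxy for a gene: mean over SNPs of the
    unbiased per-site heterozygosity 2*p*q*n/(n-1), with p the pooled
    (both-sex) sample frequency and n = N_m + N_f alleles."""
    n_m = np.asarray(n_m, dtype=float)
    N_m = np.asarray(N_m, dtype=float)
    n_f = np.asarray(n_f, dtype=float)
    N_f = np.asarray(N_f, dtype=float)
    n = N_m + N_f
    if np.any(n < 2):
        raise ValueError("gene_pi requires at least 2 sampled alleles per SNP")
    p = (n_m + n_f) / n
    pi_site = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(np.mean(pi_site))


def filter_snps(counts: pd.DataFrame, max_monomorphic_pops: int = 5):
    """Apply the two SNP filters used before computing divergence.

    Rule 1: a SNP is excluded from one population if its pooled (both-sex)
    minor-allele count in that population equals 1 (a singleton).
    Rule 2: a SNP is removed from *all* populations if it is monomorphic
    (pooled) in more than ``max_monomorphic_pops`` populations; exactly
    that many is retained.

    Returns ``(filtered, report)`` where ``report`` counts removals by rule.
    """
    df = counts.copy()
    total = df["n_m"] + df["n_f"]
    N = df["N_m"] + df["N_f"]
    minor = np.minimum(total, N - total)

    mono_by_snp = (
        pd.DataFrame({"snp_id": df["snp_id"], "mono": minor == 0})
        .groupby("snp_id")["mono"]
        .sum()
    )
    snps_removed = set(mono_by_snp.index[mono_by_snp > max_monomorphic_pops])

    singleton = (minor == 1) & ~df["snp_id"].isin(snps_removed)
    keep = ~singleton & ~df["snp_id"].isin(snps_removed)
    report = {
        "n_input_rows": int(len(df)),
        "n_singleton_rows_excluded": int(singleton.sum()),
        "n_snps_removed_monomorphic": len(snps_removed),
        "n_rows_removed_monomorphic_rule": int(df["snp_id"].isin(snps_removed).sum()),
        "n_output_rows": int(keep.sum()),
    }
    return df.loc[keep].reset_index(drop=True), report


def snp_divergence_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP frequencies and divergence statistics for a counts table.

    Adds p_m, p_f, p, fst, da, heterozygosity (pq), fst_scaled_pq and
    fst_scaled_2pq columns.  Monomorphic or insufficient-data SNPs carry
    NaN in the statistics.
    """
    df = counts.copy()
    p_m, p_f, p, _q = compute_sex_freqs(
        df["n_m"].to_numpy(), df["N_m"].to_numpy(),
        df["n_f"].to_numpy(), df["N_f"].to_numpy(),
    )
    df["p_m"], df["p_f"], df["p"] = p_m, p_f, p
    df["fst"] = sex_fst_snp(p_m, p_f, p)
    df["da"] = sex_da_snp(p_m, p_f)
    df["heterozygosity"] = p * (1.0 - p)
    df["fst_scaled_pq"] = heterozygosity_scaled_fst(df["fst"].to_numpy(), p, "pq")
    df["fst_scaled_2pq"] = heterozygosity_scaled_fst(df["fst"].to_numpy(), p, "2pq")
    return df


def gene_divergence_table(counts: pd.DataFrame, value: str = "fst") -> pd.DataFrame:
    """Aggregate per-SNP statistics to (gene, population) rows.

    ``value`` selects the per-SNP column to summarise (fst, da,
    fst_scaled_pq, fst_scaled_2pq).  Output columns: gene_id, population,
    mean_<value>, median_<value>, max_<value>, pi, n_snps.  Genes with no
    informative SNP in a population are dropped.
    """
    snp = counts if value in counts.columns else snp_divergence_table(counts)
    snp = snp.copy()
    n = (snp["N_m"] + snp["N_f"]).to_numpy(dtype=float)
    p_pool = (snp["n_m"] + snp["n_f"]).to_numpy(dtype=float) / n
    snp["_pi_site"] = 2.0 * p_pool * (1.0 - p_pool) * n / (n - 1.0)

    grouped = snp.groupby(["gene_id", "population"], sort=True)
    agg = grouped[value].agg(["mean", "median", "max", "count"])
    agg.columns = [f"mean_{value}", f"median_{value}", f"max_{value}", "n_snps"]
    agg["pi"] = grouped["_pi_site"].mean()
    dropped = int((agg["n_snps"] == 0).sum())
    if dropped:
        logger.warning("%d gene-population rows dropped: no informative SNPs", dropped)
    agg = agg[agg["n_snps"] > 0].reset_index()
    agg["n_snps"] = agg["n_snps"].astype(int)
    cols = ["gene_id", "population", f"mean_{value}", f"median_{value}",
            f"max_{value}", "pi", "n_snps"]
    return agg[cols]
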