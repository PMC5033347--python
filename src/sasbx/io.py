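"""Readers and writers for the package's tab-separated interfaces.

Formats:
  counts TSV    population, gene_id, snp_id, chrom, pos (1-based), allele,
                n_m, N_m, n_f, N_f (header required)
  expression    gene_id rows x sample_id columns of abundances
  samples TSV   sample_id, sex (M/F), tissue
  genes BED     chrom, start, end, gene_id (0-based, half-open)
  VCF           standard VCF plus a two-column sample map (sample_id, sex)

A SNP at 1-based position P belongs to a gene iff P - 1 lies in
[start, end) of the gene's BED interval.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

COUNTS_COLUMNS = ["population", "gene_id", "snp_id", "chrom", "pos", "allele",
                  "n_m", "N_m", "n_f", "N_f"]


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts TSV {path} missing columns: {missing}")
    return df


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"expression TSV {path} must have a gene_id column")
    return df


def read_samples_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "sex", "tissue") if c not in df.columns]
    if missing:
        raise ValueError(f"samples TSV {path} missing columns: {missing}")
    bad = set(df["sex"]) - {"M", "F"}
    if bad:
        raise ValueError(f"sex column must be M/F, found {sorted(bad)}")
    return df


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id"],
                     usecols=[0, 1, 2, 3])
    return df


def assign_snps_to_genes(snps: pd.DataFrame, bed: pd.DataFrame) -> pd.DataFrame:
    """Attach gene_id to SNPs by BED-interval overlap.

    ``snps`` needs chrom and 1-based pos columns.  A SNP overlapping
    several transcribed regions is assigned to each (one row per match);
    unassigned SNPs are dropped.
    """
    out = []
    for chrom, sub in snps.groupby("chrom", sort=False):
        intervals = bed[bed["chrom"] == chrom]
        if intervals.empty:
            continue
        pos0 = sub["pos"].to_numpy() - 1  # 0-based
        for _, g in intervals.iterrows():
            hit = (pos0 >= g["start"]) & (pos0 < g["end"])
            if hit.any():
                m = sub.loc[hit].copy()
                m["gene_id"] = g["gene_id"]
                out.append(m)
    if not out:
        return snps.iloc[0:0].assign(gene_id=pd.Series(dtype=object))
    return pd.concat(out, ignore_index=True)


def read_vcf_counts(vcf_path, sample_map, population: str = "pop") -> pd.DataFrame:
    """Convert VCF genotypes to per-sex allele counts at biallelic SNPs.

    ``sample_map``: DataFrame or path of a two-column TSV (sample_id,
    sex in {M, F}).  The ALT allele is the designated allele; missing
    genotypes are dropped from the totals; non-biallelic records skipped.
    """
    from cyvcf2 import VCF

    if not isinstance(sample_map, pd.DataFrame):
        sample_map = pd.read_csv(sample_map, sep="\t")
    sex_of = dict(zip(sample_map["sample_id"], sample_map["sex"]))

    vcf = VCF(str(vcf_path))
    is_male = np.array([sex_of.get(s) == "M" for s in vcf.samples])
    is_female = np.array([sex_of.get(s) == "F" for s in vcf.samples])
    rows = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gt = np.array(var.genotypes)[:, :2]  # (samples, 2 alleles)
        valid = gt >= 0
        alt = (gt == 1) & valid
        rows.append({
            "population": population,
            "gene_id": "",
            "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": var.CHROM,
            "pos": var.POS,
            "allele": var.ALT[0],
            "n_m": int(alt[is_male].sum()),
            "N_m": int(valid[is_male].sum()),
            "n_f": int(alt[is_female].sum()),
            "N_f": int(valid[is_female].sum()),
        })
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def write_tsv(df: pd.DataFrame, path, sort_by=None) -> None:
    """Deterministic TSV output: optional sort, 10 significant digits."""
    if sort_by:
        df = df.sort_values(sort_by, kind="stable")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
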