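"""End-to-end orchestration: counts + expression -> Twin-Peaks report.

Stages: (optional) synthetic-data generation -> SNP filtering -> per-SNP
divergence -> per-gene aggregation -> Δ computation -> merge -> quartic
Twin-Peaks fit with permutation p and bootstrap CIs -> small-Δ quadratic
check -> heterozygosity-scaled refit -> prevalence summary -> optional
per-SNP FDR table.  Outputs are deterministic TSVs plus a JSON report
validated against the shipped pydantic schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__
from .divergence import filter_snps, gene_divergence_table, snp_divergence_table
from .expression import delta_table
from .io import read_counts_tsv, read_expression_tsv, read_samples_tsv, write_tsv
from .power import bh_fdr, persnp_test
from .simulate import SimConfig, simulate_study
from .twinpeaks import (TwinPeaksRegressor, bootstrap_curves, permutation_test,
                        quadratic_small_delta)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs (file paths or a simulation spec), options, and output dir."""

    counts_path: str | None = None
    expression_path: str | None = None
    samples_path: str | None = None
    simulate: SimConfig | None = None
    aggregation: str = "mean"        # mean | median | max
    scaling: str = "none"            # none | pq | 2pq
    n_perm: int = 1000
    n_boot: int = 1000
    small_delta_window: tuple = (-0.52, 0.72)
    prevalence_band: tuple = (0.25, 0.75)
    run_persnp_fdr: bool = False
    persnp_test_method: str = "chisq"
    max_monomorphic_pops: int = 5
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        has_files = self.counts_path is not None
        if has_files and self.simulate is not None:
            raise ValueError("provide either input paths or a simulate spec, not both")
        if not has_files and self.simulate is None:
            raise ValueError("provide input paths or a simulate spec")


class CurveReport(BaseModel):
    degree: int
    coefficients: list[float]
    p_anova: float
    leading_negative: bool
    n_derivative_roots: int
    is_twin_peaks: bool
    peaks: list[float]
    valley: float | None
    permutation_p: float | None = None
    n_perm: int | None = None
    bootstrap_pattern_fraction: float | None = None
    peak_location_ci: dict | None = None


class QuadraticReport(BaseModel):
    quadratic_coefficient: float
    se: float
    p_value: float
    fraction_in_window: float
    n_in_window: int


class PipelineReport(BaseModel):
    """Machine-readable run summary; the pydantic model is the schema."""

    package_version: str
    seed: int
    n_genes: int
    n_rows: int
    filter_report: dict
    quartic: CurveReport
    quadratic_small_delta: QuadraticReport
    het_scaled_quartic: CurveReport | None
    prevalence_fraction: float
    detected: bool
    persnp_fdr_n_significant: int | None = None


def _curve_report(delta, response, gene_ids, n_perm, n_boot, seed,
                  with_resampling=True) -> tuple[CurveReport, dict | None]:
    reg = TwinPeaksRegressor(degree=4).fit(delta, response)
    rep = CurveReport(
        degree=4,
        coefficients=[float(c) for c in reg.coef_],
        p_anova=float(reg.p_anova_),
        leading_negative=bool(reg.leading_negative_),
        n_derivative_roots=int(reg.n_derivative_roots_),
        is_twin_peaks=bool(reg.is_twin_peaks_),
        peaks=[float(x) for x in reg.peaks_],
        valley=float(reg.valley_) if reg.valley_ is not None else None,
    )
    density = None
    if with_resampling:
        perm = permutation_test(delta, response, n_perm=n_perm, seed=seed)
        rep.permutation_p = perm.p_value
        rep.n_perm = perm.n_replicates
        boot = bootstrap_curves(delta, response, gene_ids, n_boot=n_boot, seed=seed + 1)
        rep.bootstrap_pattern_fraction = boot.pattern_count / max(boot.n_replicates, 1)
        rep.peak_location_ci = boot.peak_location_ci
        density = boot.curve_density
    return rep, density


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages; write TSV/JSON outputs if an outdir is set."""
    cfg = config
    if cfg.simulate is not None:
        study = simulate_study(cfg.simulate)
        counts, expression, samples = study.counts, study.expression, study.samples
    else:
        for name in ("counts_path", "expression_path", "samples_path"):
            p = getattr(cfg, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        counts = read_counts_tsv(cfg.counts_path)
        expression = read_expression_tsv(cfg.expression_path)
        samples = read_samples_tsv(cfg.samples_path)

    counts, filter_report = filter_snps(counts, cfg.max_monomorphic_pops)
    snp = snp_divergence_table(counts)
    value = {"none": "fst", "pq": "fst_scaled_pq", "2pq": "fst_scaled_2pq"}[cfg.scaling]
    gene = gene_divergence_table(snp, value="fst")
    deltas = delta_table(expression, samples)

    merged = gene.merge(deltas[["gene_id", "delta"]], on="gene_id", how="inner")
    n_unmatched = gene["gene_id"].nunique() - merged["gene_id"].nunique()
    if n_unmatched:
        logger.info("%d genes without Δ dropped from the regression", n_unmatched)
    merged = merged.dropna(subset=["delta", f"{cfg.aggregation}_fst"])
    merged = merged.sort_values(["gene_id", "population"], kind="stable").reset_index(drop=True)

    response = merged[f"{cfg.aggregation}_fst"].to_numpy()
    delta = merged["delta"].to_numpy()
    genes = merged["gene_id"].to_numpy()

    quartic, density = _curve_report(delta, response, genes,
                                     cfg.n_perm, cfg.n_boot, cfg.seed)
    quad = QuadraticReport(**quadratic_small_delta(delta, response, cfg.small_delta_window))

    # heterozygosity-controlled refit: per-SNP FST/pq aggregated the same way
    het_gene = gene_divergence_table(snp, value="fst_scaled_pq")
    het_merged = het_gene.merge(deltas[["gene_id", "delta"]], on="gene_id", how="inner")
    het_merged = het_merged.dropna(subset=["delta", f"{cfg.aggregation}_fst_scaled_pq"])
    het_report, _ = _curve_report(
        het_merged["delta"].to_numpy(),
        het_merged[f"{cfg.aggregation}_fst_scaled_pq"].to_numpy(),
        het_merged["gene_id"].to_numpy(),
        cfg.n_perm, cfg.n_boot, cfg.seed, with_resampling=False,
    )

    per_gene_delta = deltas.dropna(subset=["delta"])
    band = cfg.prevalence_band
    prevalence = float(((per_gene_delta["delta"].abs() > band[0])
                        & (per_gene_delta["delta"].abs() < band[1])).mean())

    n_sig = None
    if cfg.run_persnp_fdr:
        pvals = np.array([
            persnp_test(r.n_m, r.N_m, r.n_f, r.N_f, method=cfg.persnp_test_method)
            for r in counts.itertuples()
        ])
        n_sig = int((bh_fdr(pvals) <= 0.05).sum())

    report = PipelineReport(
        package_version=__version__,
        seed=cfg.seed,
        n_genes=int(merged["gene_id"].nunique()),
        n_rows=int(len(merged)),
        filter_report=filter_report,
        quartic=quartic,
        quadratic_small_delta=quad,
        het_scaled_quartic=het_report,
        prevalence_fraction=prevalence,
        detected=bool(quartic.is_twin_peaks
                      and quartic.permutation_p is not None
                      and quartic.permutation_p < 0.05),
        persnp_fdr_n_significant=n_sig,
    )

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(merged, out / "gene_delta_fst.tsv", sort_by=["gene_id", "population"])
        if density is not None:
            dens = pd.DataFrame(density["density"],
                                columns=[f"{d:.4f}" for d in density["delta_grid"]])
            dens.insert(0, "response_bin_low", density["response_edges"][:-1])
            write_tsv(dens, out / "curve_density.tsv")
        (out / "report.json").write_text(report.model_dump_json(indent=2))
        (out / "run.log").write_text(
            f"sasbx {__version__}\nseed {cfg.seed}\n"
            f"numpy {np.__version__}\npandas {pd.__version__}\n"
        )
    return report


def validate_report(path) -> PipelineReport:
    """Parse and validate a report.json against the shipped schema."""
    return PipelineReport.model_validate(json.loads(Path(path).read_text()))
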