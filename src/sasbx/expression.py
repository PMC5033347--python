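"""The Δ sex-bias statistic from replicate expression measurements.

For a gene with summary transcript abundances ``m`` (males) and ``f``
(females), the normalized expression difference is

    Δ = (m - f) / (m + f)

Δ = -1 for a gene expressed only in females, 0 for unbiased expression and
+1 for male-only expression.  For weak bias Δ is approximately half the
log expression difference, ½·ln(m/f), and is therefore nearly perfectly
correlated with the familiar log2 expression ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionProfile:
    """Per-sample abundances for one gene, split by sex, with tissue labels."""

    gene_id: str
    male_values: list = field(default_factory=list)
    female_values: list = field(default_factory=list)
    male_tissues: list = field(default_factory=list)
    female_tissues: list = field(default_factory=list)


def delta_statistic(m, f):
    """Δ = (m - f)/(m + f); NaN (missing marker) where m + f = 0."""
    m = np.asarray(m, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(m < 0) or np.any(f < 0):
        raise ValueError("abundances must be non-negative")
    tot = m + f
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(tot > 0, (m - f) / np.where(tot > 0, tot, 1), np.nan)
    return delta[()] if delta.ndim == 0 else delta


def aggregate_expression(profile: ExpressionProfile, tissue_set_m, tissue_set_f):
    """Summarise a gene's abundance per sex: mean over samples within each
    requested tissue, then the unweighted mean across tissues (each tissue
    weighted equally, regardless of its sample count)."""

    def _per_sex(values, tissues, wanted, sex):
        wanted = list(wanted)
        if not wanted:
            raise ValueError(f"empty tissue set for {sex}")
        values = np.asarray(values, dtype=float)
        tissues = np.asarray(tissues, dtype=object)
        tissue_means = []
        for t in wanted:
            mask = tissues == t
            if not mask.any():
                raise ValueError(f"no {sex} samples for requested tissue {t!r}")
            tissue_means.append(float(values[mask].mean()))
        return float(np.mean(tissue_means))

    m = _per_sex(profile.male_values, profile.male_tissues, tissue_set_m, "male")
    f = _per_sex(profile.female_values, profile.female_tissues, tissue_set_f, "female")
    return m, f


def delta_table(expression: pd.DataFrame, samples: pd.DataFrame,
                tissue_set_m=None, tissue_set_f=None) -> pd.DataFrame:
    """Per-gene Δ table from an expression matrix and sample metadata.

    ``expression``: genes in rows (index or ``gene_id`` column), samples in
    columns.  ``samples``: columns sample_id, sex (M/F), tissue.  Tissue
    sets default to every tissue observed in each sex.  Output columns:
    gene_id, delta, total, n_male_samples, n_female_samples.  Genes with
    zero total expression get a missing Δ (logged), to be excluded from
    regressions.
    """
    expr = expression.set_index("gene_id") if "gene_id" in expression.columns else expression
    samples = samples.copy()
    known = samples["sample_id"].isin(expr.columns)
    samples = samples[known]
    male = samples[samples["sex"] == "M"]
    female = samples[samples["sex"] == "F"]
    if tissue_set_m is None:
        tissue_set_m = sorted(male["tissue"].unique())
    if tissue_set_f is None:
        tissue_set_f = sorted(female["tissue"].unique())

    def _sex_summary(meta, wanted, sex):
        per_tissue = []
        for t in wanted:
            ids = meta.loc[meta["tissue"] == t, "sample_id"].tolist()
            if not ids:
                raise ValueError(f"no {sex} samples for requested tissue {t!r}")
            per_tissue.append(expr[ids].mean(axis=1))
        return pd.concat(per_tissue, axis=1).mean(axis=1)

    m = _sex_summary(male, tissue_set_m, "male")
    f = _sex_summary(female, tissue_set_f, "female")
    delta = delta_statistic(m.to_numpy(), f.to_numpy())
    n_zero = int(np.isnan(delta).sum())
    if n_zero:
        logger.warning("%d genes with zero total expression: Δ missing", n_zero)
    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "delta": delta,
            "total": (m + f).to_numpy(),
            "n_male_samples": len(male),
            "n_female_samples": len(female),
        }
    ).reset_index(drop=True)
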