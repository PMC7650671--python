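"""qPCR relative quantification: ΔCt, 2^ΔCt, normal-median normalization.

Expression of a target gene is quantified relative to an endogenous
reference gene (default *TBP*): replicate Ct values are averaged per
sample and gene, ΔCt = mean Ct(reference) − mean Ct(target), and the
N-fold value is 2^ΔCt (100% amplification efficiency assumed).  N-fold
values are then rescaled so the median over a designated set of normal
tissues equals exactly 1, making tumor values directly readable as
fold-change over normal tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENE = "TBP"


@dataclass(frozen=True)
class NormalizedExpression:
    """Normal-median-scaled N-fold expression of one gene in one sample."""

    sample_id: str
    gene: str
    nfold: float

    def __post_init__(self) -> None:
        if self.nfold < 0:
            raise ValueError(f"nfold must be non-negative, got {self.nfold}")


def relative_expression(ct_gene: float, ct_ref: float) -> float:
    """Pre-normalization N-fold value 2^(Ct_ref − Ct_gene).

    Equal Ct gives 1; each cycle the target crosses threshold earlier
    than the reference doubles the value.
    """
    if not (np.isfinite(ct_gene) and np.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_ref - ct_gene))


def mean_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Ct values per (sample, gene).

    *ct_table* columns: ``sample_id, gene, ct``; one row per replicate.
    Non-finite T (undetermined wells) are treated as missing and
    excluded; replicate dispersion is logged, not modeled.
    """
    required = {"sample_id", "gene", "ct"}
    if missing := required - set(ct_table.columns):
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    tab = ct_table.copy()
    tab["ct"] = pd.to_numeric(tab["ct"], errors="coerce")
    n_bad = int(tab["ct"].isna().sum())
    if n_bad:
        logger.warning("%d undetermined Ct well(s) excluded", n_bad)
    tab = tab.dropna(subset=["ct"])
    agg = tab.groupby(["sample_id", "gene"], as_index=False)["ct"].agg(["mean", "std", "count"])
    wide = agg.rename(columns={"mean": "ct"})
    spread = wide.loc[wide["std"].fillna(0) > 0.5]
    for rec in spread.itertuples():
        logger.info("replicate Ct spread %.2f for %s / %s", rec.std, rec.sample_id, rec.gene)
    return wide[["sample_id", "gene", "ct", "count"]]


def nfold_table(ct_table: pd.DataFrame,
                reference_gene: str = DEFAULT_REFERENCE_GENE) -> pd.DataFrame:
    """Per-sample, per-gene pre-normalization N-fold values from raw Ct.

    Samples lacking a reference-gene Ct are skipped with a warning;
    Ct values at or below 0 entered as floored expression (nfold given
    directly as 0 on input) are not produced here — a missing pair stays
    missing.
    """
    means = mean_ct(ct_table)
    ref = means.loc[means["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = means.loc[means["gene"] != reference_gene]
    rows = []
    for rec in targets.itertuples():
        if rec.sample_id not in ref.index:
            logger.warning("sample %s has no %s Ct; skipped", rec.sample_id, reference_gene)
            continue
        rows.append(
            {"sample_id": rec.sample_id, "gene": rec.gene,
             "nfold": relative_expression(rec.ct, float(ref[rec.sample_id]))}
        )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "nfold"])


def normalize_to_reference_cohort(values: pd.DataFrame,
                                  normal_ids: set[str] | list[str]) -> pd.DataFrame:
    """Rescale N-fold values so the normal-tissue median is exactly 1.

    *values* columns: ``sample_id, gene, nfold``.  Normalization is
    per gene; even-cardinality medians use the midpoint convention
    (numpy default).  Raises when a gene has no normal-tissue value.
    """
    normal_ids = set(normal_ids)
    if missing := {"sample_id", "gene", "nfold"} - set(values.columns):
        raise ValueError(f"nfold table missing columns {sorted(missing)}")
    out = []
    for gene, sub in values.groupby("gene"):
        normals = sub.loc[sub["sample_id"].isin(normal_ids), "nfold"]
        if normals.empty:
            raise ValueError(f"no normal-tissue value for gene {gene!r}")
        med = float(np.median(normals))
        if med <= 0:
            raise ValueError(f"normal-tissue median for gene {gene!r} is {med}, cannot scale")
        sub = sub.assign(nfold=sub["nfold"] / med)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def expression_pipeline(ct_table: pd.DataFrame, normal_ids: set[str] | list[str],
                        reference_gene: str = DEFAULT_REFERENCE_GENE) -> pd.DataFrame:
    """Raw Ct table → normalized N-fold table: replicate averaging,
    ΔCt against the reference gene, 2^ΔCt, normal-median scaling."""
    return normalize_to_reference_cohort(nfold_table(ct_table, reference_gene), normal_ids)
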