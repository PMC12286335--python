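"""Polygenic risk scores from genotype dosages and a risk-variant table.

The score is the per-sample sum of risk-allele dosages over a panel of
risk variants (optionally effect-size weighted), dichotomized into a
high-PRS group — the top 5% of scores by default — and a low-PRS group.
Dosage input is a samples x variants table in [0, 2] on the risk-allele
scale, read from TSV or from a VCF with per-genotype ``DS`` dosages
(hard ``GT`` calls as fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RiskVariantTable",
    "compute_prs",
    "categorize_prs",
    "read_variant_table",
    "read_dosage_tsv",
    "read_dosage_vcf",
    "prs_results",
]


@dataclass
class RiskVariantTable:
    """Risk-variant panel: ids, risk alleles and (optional) effect weights."""

    table: pd.DataFrame  # columns: variant_id, risk_allele, weight

    def __post_init__(self) -> None:
        required = {"variant_id", "risk_allele", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        if self.table["variant_id"].duplicated().any():
            dups = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant ids: {sorted(set(dups))}")
        if not np.all(np.isfinite(self.table["weight"].to_numpy(dtype=float))):
            raise ValueError("variant weights must be finite")

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def weights(self) -> pd.Series:
        return self.table.set_index("variant_id")["weight"].astype(float)


def read_variant_table(path) -> RiskVariantTable:
    """Read a PLINK-score-like whitespace-delimited file: ID ALLELE [WEIGHT].

    A header row is detected by a non-numeric third column; the weight
    column defaults to 1.0 when absent.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("variant score file needs at least ID and ALLELE columns")
    first = df.iloc[0]
    looks_like_header = df.shape[1] >= 3 and not _is_number(first.iloc[2])
    if df.shape[1] == 2 and first.iloc[0].upper() in ("ID", "SNP", "VARIANT_ID"):
        looks_like_header = True
    if looks_like_header:
        df = df.iloc[1:].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "variant_id": df.iloc[:, 0],
            "risk_allele": df.iloc[:, 1],
            "weight": pd.to_numeric(df.iloc[:, 2], errors="raise")
            if df.shape[1] >= 3
            else 1.0,
        }
    )
    return RiskVariantTable(out)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def read_dosage_tsv(path) -> pd.DataFrame:
    """Read a dosage TSV: rows = samples (first column id), columns = variants."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_dosage_range(df)
    return df


def read_dosage_vcf(path, variants: RiskVariantTable | None = None) -> pd.DataFrame:
    """Read dosages from a VCF into a samples x variants table.

    Uses the per-genotype ``DS`` FORMAT field when present, else counts
    ALT alleles from hard ``GT`` calls.  Dosages are oriented to the risk
    allele when a variant table is supplied: if the risk allele is the
    REF allele the dosage is flipped to ``2 - ds``; variants whose risk
    allele matches neither REF nor ALT are dropped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    risk = (
        variants.table.set_index("variant_id")["risk_allele"] if variants is not None else None
    )
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        except (TypeError, KeyError):
            gts = np.asarray(rec.gt_types)  # 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
            ds = np.where(gts == 3, 2.0, np.where(gts == 1, 1.0, 0.0))
        if risk is not None and vid in risk.index:
            allele = risk.loc[vid]
            if allele == rec.REF:
                ds = 2.0 - ds
            elif allele not in rec.ALT:
                warnings.warn(
                    f"variant {vid}: risk allele {allele} matches neither REF nor ALT; dropped"
                )
                continue
        cols[vid] = ds
    df = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    _check_dosage_range(df)
    return df


def _check_dosage_range(df: pd.DataFrame) -> None:
    vals = df.to_numpy(dtype=float)
    if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
        raise ValueError("dosages must lie in [0, 2]")


def compute_prs(
    dosages: pd.DataFrame,
    variants: RiskVariantTable,
    weighted: bool = False,
    missing: str = "strict",
) -> pd.Series:
    """Per-sample polygenic risk score.

    Unweighted (default): the sum of risk-allele dosages over the panel.
    Weighted: each dosage multiplied by the variant's effect weight.

    ``missing='strict'`` raises if any panel variant is absent from the
    dosage matrix; ``'lenient'`` warns and sums over the intersection
    (remaining weights are never rescaled — rescaling would silently
    change what the score measures).
    """
    _check_dosage_range(dosages)
    ids = variants.variant_ids
    present = [v for v in ids if v in dosages.columns]
    absent = sorted(set(ids) - set(present))
    if absent:
        if missing == "strict":
            raise KeyError(f"variants absent from dosage matrix: {absent}")
        if missing != "lenient":
            raise ValueError(f"unknown missing policy {missing!r}")
        warnings.warn(f"{len(absent)} panel variants absent from dosage matrix; excluded")
    sub = dosages[present].astype(float)
    if weighted:
        w = variants.weights.loc[present]
        scores = sub.mul(w, axis=1).sum(axis=1)
    else:
        scores = sub.sum(axis=1)
    scores.name = "prs"
    return scores


def categorize_prs(scores: pd.Series | np.ndarray, high_fraction: float = 0.05) -> pd.Series:
    """Split scores into 'high' (top ``high_fraction``) and 'low' groups.

    The threshold is the empirical ``1 - high_fraction`` quantile under
    the linear-interpolation convention (numpy default, Hyndman-Fan
    type 7); samples with score >= threshold are 'high', so threshold
    ties all land in the high group.  With n distinct scores and no
    ties this yields ceil(high_fraction * (n - 1)) high samples (one
    more when the type-7 quantile position lands exactly on an order
    statistic).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot categorize an empty score vector")
    if not 0.0 < high_fraction < 1.0:
        raise ValueError("high_fraction must lie strictly in (0, 1)")
    threshold = np.quantile(arr, 1.0 - high_fraction, method="linear")
    cats = np.where(arr >= threshold, "high", "low")
    index = scores.index if isinstance(scores, pd.Series) else None
    return pd.Series(cats, index=index, name="prs_category")


def prs_results(
    dosages: pd.DataFrame,
    variants: RiskVariantTable,
    weighted: bool = False,
    high_fraction: float = 0.05,
) -> pd.DataFrame:
    """Convenience: scores plus high/low category as a tidy table."""
    scores = compute_prs(dosages, variants, weighted=weighted)
    cats = categorize_prs(scores, high_fraction=high_fraction)
    return pd.DataFrame({"sample_id": scores.index, "score": scores.to_numpy(),
                         "category": cats.to_numpy()}).reset_index(drop=True)
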