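"""Transcriptomic signature scoring and risk/immune integration.

Implements the Immune Activity Score (mean expression of immune effector
genes), direction-weighted therapy-sensitivity signature scores, threshold
responder calls, and the four-way risk x immune stratification.

Default gene sets ship as editable JSON in ``spinepath/data/gene_sets.json``;
they are illustrative defaults, not a canonical list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    weights: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene set must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        if not self.weights:
            self.weights = [1.0] * len(self.genes)
        if len(self.weights) != len(self.genes):
            raise ValueError("weights must align with genes")


def default_gene_sets() -> dict[str, GeneSet]:
    """Gene sets shipped with the package (immune, RANKL, steroid, chemo)."""
    raw = json.loads(resources.files("spinepath.data").joinpath("gene_sets.json").read_text())
    return {
        name: GeneSet(name=name, genes=entry["genes"], weights=entry.get("weights", []))
        for name, entry in raw.items()
    }


def load_expression(path_or_buffer, log2_transform: bool = False) -> pd.DataFrame:
    """Load and validate a genes x samples TSV expression matrix."""
    df = pd.read_csv(path_or_buffer, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols: {dups}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(f"non-numeric expression value at gene {gene!r}, sample {col!r}")
    df = df.astype(np.float64)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if log2_transform:
        df = np.log2(df + 1.0)
    return df


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples; constant genes map to 0 with a warning."""
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene row(s): z-score set to 0")
    sd = sd.replace(0.0, 1.0)
    return expr.sub(mu, axis=0).div(sd, axis=0)


def _resolve_set(expr: pd.DataFrame, gene_set: GeneSet, min_overlap: float = 0.5):
    present = [(g, w) for g, w in zip(gene_set.genes, gene_set.weights) if g in expr.index]
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} found in matrix")
    missing = [g for g in gene_set.genes if g not in expr.index]
    if missing:
        warnings.warn(f"set {gene_set.name!r}: missing genes {missing}")
    if len(present) / len(gene_set.genes) < min_overlap:
        warnings.warn(
            f"set {gene_set.name!r}: overlap {len(present)}/{len(gene_set.genes)} "
            f"below the {min_overlap:.0%} minimum"
        )
    return present


def immune_activity_score(
    expr: pd.DataFrame, immune_set: GeneSet, zscore: bool = False, min_overlap: float = 0.5
) -> pd.Series:
    """Per-sample mean expression of the immune effector set."""
    present = _resolve_set(expr, immune_set, min_overlap)
    genes = [g for g, _ in present]
    mat = zscore_genes(expr.loc[genes]) if zscore else expr.loc[genes]
    return mat.mean(axis=0).rename("immune_activity")


def signature_score(
    expr: pd.DataFrame, gene_set: GeneSet, zscore: bool = True, min_overlap: float = 0.5
) -> pd.Series:
    """Direction-weighted mean of (optionally z-scored) member genes."""
    present = _resolve_set(expr, gene_set, min_overlap)
    genes = [g for g, _ in present]
    weights = np.array([w for _, w in present])
    mat = zscore_genes(expr.loc[genes]) if zscore else expr.loc[genes]
    return (mat.mul(weights, axis=0).sum(axis=0) / len(genes)).rename(gene_set.name)


def classify_responder(scores: pd.Series, threshold: float | None = None) -> tuple[pd.Series, dict]:
    """Responder = score strictly above threshold (tie -> non-responder).

    Default threshold is the cohort median.  Returns the flags and a rule
    record from which the flags can be reconstructed exactly.
    """
    used = float(scores.median()) if threshold is None else float(threshold)
    flags = scores.where(scores.notna()).gt(used)
    flags[scores.isna()] = pd.NA
    rule = {
        "score": scores.name or "score",
        "threshold": used,
        "threshold_source": "cohort_median" if threshold is None else "configured",
        "rule": "responder iff score > threshold; ties are non-responders",
    }
    return flags.rename("responder"), rule


def risk_immune_strata(
    risk: pd.Series,
    immune: pd.Series,
    risk_cut: float | None = None,
    immune_cut: float | None = None,
) -> pd.Series:
    """Four strata from risk and immune scores split at medians (or given cuts)."""
    if not risk.index.equals(immune.index):
        raise ValueError("risk and immune scores have misaligned sample ids")
    rc = float(risk.median()) if risk_cut is None else float(risk_cut)
    ic = float(immune.median()) if immune_cut is None else float(immune_cut)
    high_risk = risk > rc
    high_immune = immune > ic
    labels = np.where(
        high_risk,
        np.where(high_immune, "high-risk/high-immune", "high-risk/low-immune"),
        np.where(high_immune, "low-risk/high-immune", "low-risk/low-immune"),
    )
    return pd.Series(labels, index=risk.index, name="risk_immune_stratum")
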