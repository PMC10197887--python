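"""Bulk-expression scores: cytolytic activity, score-correlated gene
ranking (input for enrichment analyses), and gene-set mean scores."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TPM matrix from TSV (first column = gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("gene symbols must be unique")
    if (df.to_numpy() < 0).any():
        raise ValueError("expression must be nonnegative")
    return df


def cyt_score(expr: pd.DataFrame, offset: float = 0.01) -> pd.Series:
    """Cytolytic activity: geometric mean of PRF1 and GZMA expression.

    ``offset`` is a pseudo-abundance added to both genes before the
    geometric mean (0 allowed when all values are positive).
    """
    for gene in ("PRF1", "GZMA"):
        if gene not in expr.index:
            raise KeyError(f"gene {gene} absent from expression matrix")
    prf1 = expr.loc["PRF1"].astype(float) + offset
    gzma = expr.loc["GZMA"].astype(float) + offset
    score = np.sqrt(prf1 * gzma)
    score.name = "CYT"
    return score


def score_correlated_genes(
    expr: pd.DataFrame,
    score: pd.Series | Mapping[str, float],
    method: str = "spearman",
    top_n: int | None = None,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Rank genes by rank correlation of expression with a per-sample score.

    Returns a DataFrame (index = gene, column ``rho``) sorted by
    descending correlation; ``positive_only`` drops rho <= 0 before the
    ``top_n`` truncation. Used e.g. to pick the top 400 genes positively
    correlated with AMS as enrichment-analysis input.
    """
    score = pd.Series(score).astype(float)
    common = [s for s in expr.columns if s in score.index]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    if score[common].nunique() <= 1:
        raise ValueError("score is constant")
    sub = expr[common]
    if method == "spearman":
        x = sub.rank(axis=1).to_numpy(float)
        y = score[common].rank().to_numpy(float)
    elif method == "pearson":
        x = sub.to_numpy(float)
        y = score[common].to_numpy(float)
    else:
        raise ValueError(f"unknown method {method!r}")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (xc @ yc) / denom
    out = pd.DataFrame({"rho": rho}, index=sub.index).dropna()
    out = out.sort_values("rho", ascending=False, kind="stable")
    if positive_only:
        out = out[out["rho"] > 0]
    if top_n is not None:
        out = out.head(top_n)
    return out


def geneset_score(
    expr: pd.DataFrame,
    genes: Sequence[str],
    transform: str = "log1p_zscore",
) -> pd.Series:
    """Per-sample mean expression over a gene set.

    With ``transform="log1p_zscore"`` each gene is log1p-transformed
    then z-scored across samples before averaging (constant genes
    contribute 0); ``"none"`` averages raw values. Missing genes are
    dropped with a warning naming them.
    """
    present = [g for g in genes if g in expr.index]
    missing = [g for g in genes if g not in expr.index]
    if not present:
        raise KeyError(f"none of the listed genes present: {list(genes)[:10]}")
    if missing:
        warnings.warn(f"genes absent from matrix, scored without them: {missing}")
    sub = expr.loc[present].astype(float)
    if transform == "log1p_zscore":
        sub = np.log1p(sub)
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0)
        sub = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    score = sub.mean(axis=0)
    score.name = "geneset_score"
    return score
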