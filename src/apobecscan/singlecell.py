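"""Single-cell statistics: QC filtering, Ro/e group enrichment,
reference-gene correlation signatures, and seeded downsampling.

Cells arrive already annotated (cell type, sample, group); clustering
and annotation are upstream concerns. Ro/e compares each (cell type,
group) observed count ``o`` with the chi-square-style independence
expectation ``e = row_total * column_total / grand_total``; a ratio
o/e > 1 flags enrichment of that cell type in that group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import score_correlated_genes

REQUIRED_META = ("n_genes", "total_counts", "pct_mito")


def read_cell_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in REQUIRED_META if c not in df.columns]
    if missing:
        raise ValueError(f"cell metadata missing columns {missing}")
    return df


def qc_filter(
    meta: pd.DataFrame,
    gene_range: tuple[int, int] = (300, 8000),
    max_counts: int = 20000,
    max_mito_pct: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep cells with genes detected in ``gene_range``, total counts
    <= ``max_counts`` and mitochondrial percentage <= ``max_mito_pct``
    (all bounds inclusive).

    Returns (retained metadata, per-criterion removal counts; a cell
    failing several criteria is counted under each).
    """
    lo, hi = gene_range
    genes_ok = (meta["n_genes"] >= lo) & (meta["n_genes"] <= hi)
    counts_ok = meta["total_counts"] <= max_counts
    mito_ok = meta["pct_mito"] <= max_mito_pct
    keep = genes_ok & counts_ok & mito_ok
    removed = {
        "n_genes": int((~genes_ok).sum()),
        "total_counts": int((~counts_ok).sum()),
        "pct_mito": int((~mito_ok).sum()),
    }
    if keep.sum() == 0:
        warnings.warn("QC filter removed every cell")
    return meta.loc[keep].copy(), removed


@dataclass
class RoETable:
    observed: pd.DataFrame  # cell_type x group
    expected: pd.DataFrame
    ratio: pd.DataFrame
    enriched: pd.DataFrame  # boolean, ratio > 1


def roe_enrichment(
    meta: pd.DataFrame, group_key: str = "group", type_key: str = "cell_type"
) -> RoETable:
    """Observed/expected cell-type enrichment per group (Ro/e)."""
    obs = pd.crosstab(meta[type_key], meta[group_key])
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least 2 cell types and 2 groups")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("empty margin in cell-type x group table")
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.to_numpy().sum()
    exp = pd.DataFrame(exp, index=obs.index, columns=obs.columns)
    ratio = obs / exp
    return RoETable(observed=obs, expected=exp, ratio=ratio, enriched=ratio > 1)


def refgene_signature(
    expr: pd.DataFrame,
    ref_gene: str,
    candidate_genes: Sequence[str],
    top_n: int = 30,
    method: str = "spearman",
) -> pd.DataFrame:
    """Genes most correlated with a reference gene across cells.

    ``expr`` is cells x genes (e.g. log1p-normalized counts). The
    reference gene is removed from the candidate list if present.
    Returns the ``top_n`` candidates ranked by descending correlation;
    cell-level scoring of the resulting set delegates to
    :func:`apobecscan.expression.geneset_score`.
    """
    if ref_gene not in expr.columns:
        raise KeyError(f"reference gene {ref_gene} absent")
    ref = expr[ref_gene].astype(float)
    if (ref > 0).sum() < 3:
        raise ValueError(f"reference gene {ref_gene} expressed in < 3 cells")
    candidates = [g for g in candidate_genes if g != ref_gene and g in expr.columns]
    if not candidates:
        raise ValueError("no usable candidate genes")
    # genes x samples orientation for the shared correlation kernel
    ranked = score_correlated_genes(
        expr[candidates].T, ref, method=method, top_n=top_n
    )
    return ranked


def downsample_cells(
    meta: pd.DataFrame,
    per_group_n: int = 1000,
    group_key: str = "group",
    seed: int | None = None,
) -> pd.DataFrame:
    """Uniformly sample up to ``per_group_n`` cells per group without
    replacement; smaller groups are kept whole. Deterministic per seed
    (stable input order)."""
    rng = np.random.default_rng(seed)
    kept: list[pd.Index] = []
    for _, sub in meta.groupby(group_key, sort=True):
        if len(sub) <= per_group_n:
            kept.append(sub.index)
        else:
            pick = rng.choice(len(sub), size=per_group_n, replace=False)
            kept.append(sub.index[np.sort(pick)])
    order = meta.index.get_indexer(np.concatenate([k.to_numpy() for k in kept]))
    return meta.iloc[np.sort(order)].copy()
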