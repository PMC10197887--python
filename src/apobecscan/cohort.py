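"""Survival dichotomization and mutation-pathway enrichment.

The optimal-cutpoint routine scans candidate thresholds on a per-sample
score (midpoints between consecutive distinct sorted values whose
induced high/low groups both satisfy a minimum-proportion constraint)
and returns the threshold minimizing the two-group log-rank p-value.
Because the minimum over many correlated tests is anti-conservative,
a permutation-adjusted p-value is available: the observed minimum p is
referred to the null distribution of minimum p under random relabeling
of scores.

Pathway enrichment between score groups is two-stage: stage 1 screens
pathways whose cohort mutation load deviates from a gene-count-
proportional expectation (Fisher, keep p < 0.05 and BH-FDR < 0.25);
stage 2 tests each surviving pathway's 2x2 table of pathway vs
non-pathway mutation counts across the two groups, BH-adjusted over
candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact

from .io_catalog import MutationRecord

log = logging.getLogger(__name__)


def read_survival(path) -> pd.DataFrame:
    """Read a clinical CSV with columns sample, time, event, covariates."""
    df = pd.read_csv(path)
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (df["time"] < 0).any() or not df["event"].isin([0, 1]).all():
        raise ValueError("time must be >= 0 and event in {0, 1}")
    return df.set_index("sample")


def _logrank_chi2(time: np.ndarray, event: np.ndarray, in_group1: np.ndarray) -> float:
    """Two-group log-rank chi-square (1 df), observed-minus-expected form."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(bool), in_group1[order].astype(bool)
    n = len(t)
    # risk-set sizes just before each index
    at_risk = n - np.arange(n)
    ut, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=e, minlength=len(ut))  # deaths per time
    d1 = np.bincount(inv, weights=e & g, minlength=len(ut))
    # at-risk totals at first index of each unique time
    first = np.searchsorted(t, ut, side="left")
    n_at = at_risk[first].astype(float)
    # group-1 at-risk: cumulative from the right
    g_rev = np.cumsum(g[::-1])[::-1]
    n1_at = g_rev[first].astype(float)
    mask = d > 0
    d, d1, n_at, n1_at = d[mask], d1[mask], n_at[mask], n1_at[mask]
    O = d1.sum()
    E = (d * n1_at / n_at).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
    V = np.nansum(v)
    if V <= 0:
        return 0.0
    return float((O - E) ** 2 / V)


def logrank(
    survival: pd.DataFrame, labels: pd.Series | Mapping[str, str]
) -> tuple[float, float]:
    """Two-sided two-group log-rank test; returns (chi-square, p).

    ``labels`` maps samples to exactly two group names.
    """
    labels = pd.Series(labels)
    df = survival.loc[labels.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    if df["event"].sum() == 0:
        raise ValueError("no events observed")
    from lifelines.statistics import logrank_test

    m = labels == groups[0]
    res = logrank_test(
        df.loc[m.values, "time"], df.loc[~m.values, "time"],
        df.loc[m.values, "event"], df.loc[~m.values, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CutoffResult:
    cutoff: float
    labels: pd.Series  # sample -> "high" | "low"
    p_logrank: float
    scanned: list[tuple[float, float]] = field(default_factory=list)
    p_adjusted: float | None = None  # permutation-adjusted, if requested


def _candidate_cutoffs(scores: np.ndarray, minprop: float) -> np.ndarray:
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise ValueError("scores are constant; no cutoff exists")
    mids = (distinct[:-1] + distinct[1:]) / 2
    n = len(scores)
    floor = max(2, int(np.ceil(minprop * n)))  # singleton groups are untestable
    lo = np.array([(scores <= c).sum() for c in mids])
    keep = (lo >= floor) & ((n - lo) >= floor)
    cands = mids[keep]
    if len(cands) == 0:
        raise ValueError(f"no candidate cutoff satisfies minprop={minprop}")
    return cands


def _scan_min_p(
    time: np.ndarray, event: np.ndarray, scores: np.ndarray, cands: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    stats = np.array([_logrank_chi2(time, event, scores > c) for c in cands])
    pvals = chi2.sf(stats, df=1)
    return stats, pvals


def optimal_cutoff(
    score: pd.Series | Mapping[str, float],
    survival: pd.DataFrame,
    minprop: float = 0.1,
    n_permutations: int = 0,
    seed: int | None = None,
    grid: Sequence[float] | None = None,
) -> CutoffResult:
    """Survival-optimal dichotomization of a continuous score.

    Scans candidate thresholds (midpoints of distinct sorted scores, or
    an explicit ``grid``) whose groups both hold at least ``minprop`` of
    the cohort, minimizing the log-rank p. Ties in p are broken toward
    the candidate nearest the median score. With ``n_permutations > 0``
    a permutation-adjusted p-value for the selected minimum is computed
    by rerunning the scan on score-relabeled cohorts.
    """
    score = pd.Series(score).astype(float)
    df = survival.loc[score.index]
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(float)
    if event.sum() == 0:
        raise ValueError("no events observed")
    s = score.to_numpy()
    if grid is not None:
        cands = np.asarray(sorted(grid), dtype=float)
        n = len(s)
        floor = max(2, int(np.ceil(minprop * n)))
        lo = np.array([(s <= c).sum() for c in cands])
        cands = cands[(lo >= floor) & ((n - lo) >= floor)]
        if len(cands) == 0:
            raise ValueError("no grid point satisfies minprop")
    else:
        cands = _candidate_cutoffs(s, minprop)
    _, pvals = _scan_min_p(time, event, s, cands)
    pmin = pvals.min()
    best = cands[np.isclose(pvals, pmin)]
    med = np.median(s)
    cutoff = float(best[np.argmin(np.abs(best - med))])
    labels = pd.Series(
        np.where(s > cutoff, "high", "low"), index=score.index, name="group"
    )
    result = CutoffResult(
        cutoff=cutoff,
        labels=labels,
        p_logrank=float(pmin),
        scanned=list(zip(cands.tolist(), pvals.tolist())),
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            sp = rng.permutation(s)
            try:
                cp = _candidate_cutoffs(sp, minprop) if grid is None else cands
                _, pp = _scan_min_p(time, event, sp, cp)
                if pp.min() <= pmin:
                    hits += 1
            except ValueError:
                hits += 1
        result.p_adjusted = (hits + 1) / (n_permutations + 1)
    return result


@dataclass(frozen=True)
class CoxResult:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float


def cox_ph(
    survival: pd.DataFrame,
    labels: pd.Series | Mapping[str, str] | None = None,
    covariates: Sequence[str] = (),
    reference_levels: Mapping[str, str] | None = None,
    group_reference: str | None = None,
) -> list[CoxResult]:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    ``labels`` (optional) adds a binary ``group`` term whose hazard
    ratio is relative to ``group_reference`` (default: the
    lexicographically first level). Categorical covariates are
    dummy-expanded against a reference level (the most frequent, or as
    given in ``reference_levels``).
    """
    from lifelines import CoxPHFitter

    df = survival.copy()
    terms: list[str] = []
    if labels is not None:
        labels = pd.Series(labels)
        levels = sorted(labels.unique())
        if len(levels) != 2:
            raise ValueError("labels must have exactly two levels")
        ref = group_reference if group_reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"group_reference {ref!r} not a label level")
        df = df.loc[labels.index]
        df["group"] = (labels != ref).astype(int)
        terms.append("group")
    for cov in covariates:
        col = df[cov]
        if col.nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant")
        if col.dtype == object or str(col.dtype) == "category":
            ref = (reference_levels or {}).get(cov, col.mode().iloc[0])
            dummies = pd.get_dummies(col, prefix=cov, dtype=float)
            ref_col = f"{cov}_{ref}"
            dummies = dummies.drop(columns=[ref_col])
            df = pd.concat([df.drop(columns=[cov]), dummies], axis=1)
            terms.extend(dummies.columns)
        else:
            terms.append(cov)
    if df["event"].sum() == 0:
        raise ValueError("no events observed")
    if df["event"].sum() < len(terms):
        raise ValueError("fewer events than model terms")
    X = df[["time", "event"] + terms]
    arr = X[terms].to_numpy(float)
    if np.linalg.matrix_rank(arr - arr.mean(0)) < len(terms):
        raise ValueError("rank-deficient covariate matrix (duplicated column?)")
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError/Warning
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    return [
        CoxResult(
            term=t,
            hr=float(summ.loc[t, "exp(coef)"]),
            ci_low=float(summ.loc[t, "exp(coef) lower 95%"]),
            ci_high=float(summ.loc[t, "exp(coef) upper 95%"]),
            p=float(summ.loc[t, "p"]),
        )
        for t in terms
    ]


def quantile_groups(score: pd.Series | Mapping[str, float], q: float = 0.25) -> pd.Series:
    """Label samples as upper / lower / middle by score quantiles.

    upper = score >= (1-q) quantile, lower = score <= q quantile
    (linear-interpolation quantiles; ties join the extreme group).
    """
    if not 0 < q < 0.5:
        raise ValueError(f"q must be in (0, 0.5), got {q}")
    score = pd.Series(score).astype(float)
    if len(score) < 4:
        raise ValueError("need at least 4 samples")
    lo_q = score.quantile(q, interpolation="linear")
    hi_q = score.quantile(1 - q, interpolation="linear")
    labels = pd.Series("middle", index=score.index, name="quantile_group")
    labels[score <= lo_q] = "lower"
    labels[score >= hi_q] = "upper"
    if (labels != "middle").all() and lo_q == hi_q:
        raise ValueError("degenerate score distribution: tails overlap entirely")
    return labels


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    a: int  # pathway mutations, group 1 (or observed, stage 1)
    b: int  # non-pathway mutations, group 1
    c: int  # pathway mutations, group 2 (or expected, stage 1)
    d: int  # non-pathway mutations, group 2
    odds_ratio: float
    p_fisher: float
    fdr: float
    stage: int = 2


def _fisher(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def pathway_mutation_enrichment(
    records: Iterable[MutationRecord],
    gene_sets: Mapping[str, Sequence[str]],
    labels: pd.Series | Mapping[str, str],
    gene_of=None,
    universe_size: int | None = None,
    stage1_p: float = 0.05,
    stage1_fdr: float = 0.25,
) -> dict[str, list[EnrichmentResult]]:
    """Two-stage pathway mutation-enrichment between two sample groups.

    Stage 1 screens each pathway's cohort-wide mutation count against a
    gene-count-proportional expectation (2x2 Fisher of observed pathway
    vs non-pathway counts against the expected split); pathways with
    p < ``stage1_p`` and BH-FDR < ``stage1_fdr`` proceed. Stage 2 tests
    pathway vs non-pathway mutation counts between the groups by
    two-sided Fisher, BH-adjusted across candidates.

    ``gene_of`` maps a record to its gene symbol (default: the record's
    own ``gene`` field). ``universe_size`` is the gene-universe size for
    the stage-1 expectation (default: union of gene sets and mutated
    genes).
    """
    labels = pd.Series(labels)
    group_names = sorted(labels.unique())
    if len(group_names) != 2:
        raise ValueError(f"need exactly two groups, got {group_names}")
    gene_of = gene_of or (lambda r: r.gene)
    recs = [r for r in records if gene_of(r) is not None]
    by_gene: dict[str, list[MutationRecord]] = {}
    for r in recs:
        by_gene.setdefault(gene_of(r), []).append(r)
    mutated_genes = set(by_gene)
    all_set_genes = set().union(*[set(g) for g in gene_sets.values()]) if gene_sets else set()
    universe = universe_size or len(all_set_genes | mutated_genes)
    total_mut = len(recs)

    stage1: list[EnrichmentResult] = []
    p1: list[float] = []
    names: list[str] = []
    for pw, genes in gene_sets.items():
        gset = set(genes)
        obs = sum(len(by_gene.get(g, ())) for g in gset)
        if obs == 0:
            log.info("pathway %s has zero mutations; skipped", pw)
            continue
        exp = int(round(total_mut * len(gset) / universe))
        odds, p = _fisher(obs, total_mut - obs, exp, total_mut - exp)
        stage1.append(
            EnrichmentResult(pw, obs, total_mut - obs, exp, total_mut - exp,
                             odds, p, np.nan, stage=1)
        )
        p1.append(p)
        names.append(pw)
    fdr1 = bh_adjust(p1) if p1 else np.array([])
    stage1 = [
        EnrichmentResult(r.pathway, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_fisher,
                         float(f), stage=1)
        for r, f in zip(stage1, fdr1)
    ]
    candidates = [r.pathway for r in stage1 if r.p_fisher < stage1_p and r.fdr < stage1_fdr]

    g1 = set(labels.index[labels == group_names[0]])
    n_g1 = sum(1 for r in recs if r.sample in g1)
    n_g2 = total_mut - n_g1
    stage2: list[EnrichmentResult] = []
    p2: list[float] = []
    for pw in candidates:
        gset = set(gene_sets[pw])
        a = sum(1 for r in recs if gene_of(r) in gset and r.sample in g1)
        c = sum(1 for r in recs if gene_of(r) in gset and r.sample not in g1)
        b, d = n_g1 - a, n_g2 - c
        odds, p = _fisher(a, b, c, d)
        stage2.append(EnrichmentResult(pw, a, b, c, d, odds, p, np.nan, stage=2))
        p2.append(p)
    fdr2 = bh_adjust(p2) if p2 else np.array([])
    stage2 = [
        EnrichmentResult(r.pathway, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_fisher,
                         float(f), stage=2)
        for r, f in zip(stage2, fdr2)
    ]
    return {"stage1": stage1, "stage2": stage2}


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("pathway")
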