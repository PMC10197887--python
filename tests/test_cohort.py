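"""Survival dichotomization, Cox models, and pathway enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apobecscan import (
    MutationRecord,
    bh_adjust,
    cox_ph,
    logrank,
    optimal_cutoff,
    pathway_mutation_enrichment,
    quantile_groups,
)
from apobecscan.cohort import _logrank_chi2, enrichment_table
from apobecscan.simulate import gen_survival


def _surv(times, events, names=None):
    names = names or [f"P{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=pd.Index(names, name="sample"))


def test_logrank_zero_for_identical_groups():
    df = _surv([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
    labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=df.index)
    stat, p = logrank(df, labels)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_risk_table():
    """Six-subject fixture vs a manual observed-minus-expected oracle."""
    df = _surv([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 1, 1])
    labels = pd.Series(["g1"] * 3 + ["g2"] * 3, index=df.index)

    # oracle: walk the risk table at each event time
    data = sorted(zip(df["time"], df["event"], labels), key=lambda x: x[0])
    O = E = V = 0.0
    for i, (t, e, g) in enumerate(data):
        if not e:
            continue
        at_risk = [x for x in data if x[0] >= t]
        n, n1 = len(at_risk), sum(1 for x in at_risk if x[2] == "g1")
        d = sum(1 for x in at_risk if x[0] == t and x[1])
        d1 = sum(1 for x in at_risk if x[0] == t and x[1] and x[2] == "g1")
        O += d1 / d  # each event time appears d times in the loop
        E += (d * n1 / n) / d
        V += (d * (n1 / n) * (1 - n1 / n) * (n - d) / max(n - 1, 1)) / d
    expected_chi2 = (O - E) ** 2 / V

    stat, _ = logrank(df, labels)
    assert stat == pytest.approx(expected_chi2, rel=1e-9)


def test_internal_logrank_matches_lifelines():
    rng = np.random.default_rng(2)
    for _ in range(5):
        n = 40
        time = rng.exponential(10, n).round(1)  # rounding forces ties
        event = rng.integers(0, 2, n).astype(float)
        event[0] = 1
        group = rng.integers(0, 2, n).astype(bool)
        if group.all() or not group.any():
            continue
        df = _surv(time, event)
        labels = pd.Series(np.where(group, "hi", "lo"), index=df.index)
        stat, p = logrank(df, labels)
        assert _logrank_chi2(time, event, group) == pytest.approx(stat, rel=1e-8)


def test_logrank_strong_effect_significant():
    df, _ = gen_survival(200, hr=0.3, seed=5)
    labels = pd.Series(np.where(df["score"] > 1.5, "high", "low"), index=df.index)
    _, p = logrank(df, labels)
    assert p < 0.001


def test_logrank_requires_two_groups_and_events():
    df = _surv([1, 2, 3], [0, 0, 0])
    labels = pd.Series(["a", "a", "b"], index=df.index)
    with pytest.raises(ValueError, match="events"):
        logrank(df, labels)
    with pytest.raises(ValueError, match="2 groups"):
        logrank(_surv([1, 2], [1, 1]), pd.Series(["a", "a"], index=_surv([1, 2], [1, 1]).index))


def test_optimal_cutoff_recovers_planted_threshold():
    df, truth = gen_survival(200, cutoff=1.5, hr=0.3, seed=5)
    res = optimal_cutoff(df["score"], df, minprop=0.1)
    lo, hi = sorted([res.cutoff, truth.params["cutoff"]])
    between = ((df["score"] > lo) & (df["score"] <= hi)).mean()
    assert between <= 0.1  # within one decile of the planted threshold
    assert res.p_logrank == min(p for _, p in res.scanned)
    n_high = (res.labels == "high").sum()
    assert 0.1 * len(df) <= n_high <= 0.9 * len(df)


def test_optimal_cutoff_errors():
    df = _surv([1, 2], [1, 1])
    with pytest.raises(ValueError):
        optimal_cutoff(pd.Series([1.0, 2.0], index=df.index), df, minprop=0.4)
    df6 = _surv([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 0])
    with pytest.raises(ValueError, match="constant"):
        optimal_cutoff(pd.Series([2.0] * 6, index=df6.index), df6)


def test_optimal_cutoff_null_anticonservative_but_permutation_calibrated():
    """The minimum-p scan inflates type-I error; the permutation-adjusted
    p restores calibration (scaled-down null simulation)."""
    rng = np.random.default_rng(13)
    raw_hits = adj_hits = 0
    reps = 50
    for i in range(reps):
        df, _ = gen_survival(60, hr=1.0, censor_rate=0.2, seed=int(rng.integers(2**31)))
        res = optimal_cutoff(df["score"], df, minprop=0.15,
                             n_permutations=60, seed=i)
        raw_hits += res.p_logrank < 0.05
        adj_hits += res.p_adjusted < 0.05
    assert raw_hits / reps > 0.05
    se = math.sqrt(0.05 * 0.95 / reps)
    assert adj_hits / reps <= 0.05 + 2 * se + 1 / reps


def test_cox_recovers_planted_hazard_ratio():
    df, _ = gen_survival(1000, cutoff=1.5, hr=0.5, seed=9)
    labels = pd.Series(np.where(df["score"] > 1.5, "high", "low"), index=df.index)
    (res,) = cox_ph(df, labels=labels, group_reference="low")
    assert 0.4 <= res.hr <= 0.6
    assert res.ci_low <= res.hr <= res.ci_high


def test_cox_log_hr_bias_small():
    """Mean log-HR bias over simulated cohorts is < 0.05 at n=1000."""
    logs = []
    for i in range(50):
        df, _ = gen_survival(1000, cutoff=1.5, hr=0.5, censor_rate=0.2, seed=100 + i)
        labels = pd.Series(np.where(df["score"] > 1.5, "high", "low"), index=df.index)
        (res,) = cox_ph(df, labels=labels, group_reference="low")
        logs.append(math.log(res.hr))
    assert abs(np.mean(logs) - math.log(0.5)) < 0.05


def test_cox_with_covariates_and_errors():
    df, _ = gen_survival(300, hr=0.5, seed=15)
    labels = pd.Series(np.where(df["score"] > 1.5, "high", "low"), index=df.index)
    results = cox_ph(df, labels=labels, covariates=["age", "gender", "stage"],
                     group_reference="low")
    terms = [r.term for r in results]
    assert "group" in terms and "age" in terms
    assert any(t.startswith("stage_") for t in terms)
    no_events = df.copy()
    no_events["event"] = 0
    with pytest.raises(ValueError, match="events"):
        cox_ph(no_events, labels=labels)
    dup = df.copy()
    dup["age2"] = dup["age"]
    with pytest.raises(ValueError, match="rank-deficient"):
        cox_ph(dup, labels=labels, covariates=["age", "age2"])


def test_quantile_groups():
    score = pd.Series(range(1, 9), index=[f"s{i}" for i in range(8)], dtype=float)
    labels = quantile_groups(score, q=0.25)
    assert set(score[labels == "lower"]) == {1.0, 2.0}
    assert set(score[labels == "upper"]) == {7.0, 8.0}
    with pytest.raises(ValueError):
        quantile_groups(score, q=0.5)
    with pytest.raises(ValueError, match="degenerate"):
        quantile_groups(pd.Series([3.0] * 8))
    with pytest.raises(ValueError, match="4 samples"):
        quantile_groups(pd.Series([1.0, 2.0]))


def _fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric tail sum with exact rational arithmetic."""
    from fractions import Fraction

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs + p_obs * Fraction(1, 10**7):
            total += pk
    return float(min(total, 1))


def test_fisher_table_example_and_oracle():
    from scipy.stats import fisher_exact

    odds, p = fisher_exact([[30, 70], [10, 90]])
    assert odds == pytest.approx(27 / 7)
    assert p == pytest.approx(_fisher_oracle(30, 70, 10, 90), rel=1e-9)
    # equal proportions: no association
    _, p1 = fisher_exact([[10, 90], [10, 90]])
    assert p1 == pytest.approx(1.0)


def test_fisher_equals_enumeration_on_small_margins():
    """Fisher p matches the exhaustive oracle on all tables with margins <= 12."""
    from scipy.stats import fisher_exact

    for r1 in range(0, 13):
        for c1 in range(0, 13):
            for a in range(0, min(r1, c1) + 1):
                b, c = r1 - a, c1 - a
                for d in range(0, 13 - max(0, 0)):
                    if c + d > 12 or b + d > 12:
                        continue
                    if r1 == 0 or c1 == 0:
                        continue
                    _, p = fisher_exact([[a, b], [c, d]])
                    assert p == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12)


def test_bh_step_up_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
def test_bh_matches_textbook_and_permutation_invariant(pvals):
    adjusted = bh_adjust(pvals)
    # textbook step-up oracle
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    expected = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        expected[i] = running
    assert np.allclose(adjusted, expected)
    perm = np.random.RandomState(0).permutation(m)
    assert np.allclose(bh_adjust(np.asarray(pvals)[perm]), expected[perm])


def _mutation(sample, gene, pos):
    return MutationRecord(sample, "chr1", pos, "C", "T", "SNV", "nonsynonymous", gene=gene)


def test_pathway_enrichment_two_stage():
    """A pathway loaded with group-1 mutations passes stage 1 and shows
    OR > 1 in stage 2; a mutation-free pathway is skipped."""
    immune = [f"IMM{i}" for i in range(10)]
    other = [f"OTH{i}" for i in range(40)]
    gene_sets = {
        "immune": immune,
        "background": other,
        "empty": ["NEVER1", "NEVER2"],
    }
    records = []
    pos = 100
    for s in range(10):
        sample = f"H{s}"
        for g in immune * 3 + other[:5]:  # HAMS: heavy immune mutation load
            pos += 1
            records.append(_mutation(sample, g, pos))
    for s in range(10):
        sample = f"L{s}"
        for g in immune[:2] + other[:10]:
            pos += 1
            records.append(_mutation(sample, g, pos))
    labels = pd.Series(
        ["HAMS"] * 10 + ["LAMS"] * 10,
        index=[f"H{s}" for s in range(10)] + [f"L{s}" for s in range(10)],
    )
    res = pathway_mutation_enrichment(records, gene_sets, labels)
    names1 = {r.pathway for r in res["stage1"]}
    assert "empty" not in names1  # zero-mutation pathway skipped
    stage2 = {r.pathway: r for r in res["stage2"]}
    assert "immune" in stage2
    r = stage2["immune"]
    assert r.odds_ratio > 1
    assert r.p_fisher < 0.05 and r.fdr < 0.25
    assert r.odds_ratio == pytest.approx((r.a * r.d) / (r.b * r.c))
    table = enrichment_table(res["stage2"])
    assert "odds_ratio" in table.columns


def test_stage1_thresholds_are_conjunctive():
    """Both the p and the FDR threshold must hold for a pathway to reach
    stage 2: tightening the FDR bound to an unattainable level empties
    the candidate list even though stage-1 p-values stay significant."""
    immune = [f"IMM{i}" for i in range(10)]
    gene_sets = {"immune": immune, "background": [f"OTH{i}" for i in range(40)]}
    records = []
    pos = 0
    for s in range(6):
        for g in immune + [f"OTH{i}" for i in range(15)]:
            pos += 1
            records.append(_mutation(f"H{s}" if s < 3 else f"L{s}", g, pos))
    labels = pd.Series(
        ["HAMS"] * 3 + ["LAMS"] * 3,
        index=[f"H{s}" for s in range(3)] + [f"L{s}" for s in range(3, 6)],
    )
    loose = pathway_mutation_enrichment(records, gene_sets, labels)
    strict = pathway_mutation_enrichment(records, gene_sets, labels, stage1_fdr=1e-30)
    assert any(r.p_fisher < 0.05 for r in loose["stage1"])
    assert strict["stage2"] == []
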