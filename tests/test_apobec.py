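"""AMS enrichment score and YTCA/RTCA motif attribution."""

import re

import numpy as np
import pytest

from apobecscan import (
    GenomeSequence,
    MutationRecord,
    classify_apobec_motif,
    compute_ams,
    motif_table,
    revcomp,
    ytca_rtca_counts,
)
from apobecscan.simulate import gen_cohort_mutations, gen_reference, synthetic_signature_catalog


def _genome(core: str) -> GenomeSequence:
    return GenomeSequence({"c": core})


@pytest.mark.parametrize(
    "context,expect_tcw,expect_class",
    [
        ("CTCA", True, "YTCA"),
        ("ATCA", True, "RTCA"),
        ("GTCT", True, "RTCW_nonA"),
        ("TTCT", True, "YTCW_nonA"),
        ("GTCG", False, "none"),  # 3' base not W
        ("GACA", False, "none"),  # 5' base not T
    ],
)
def test_motif_classification(context, expect_tcw, expect_class):
    genome = _genome("AA" + context + "AA")  # mutated C at 1-based pos 5
    cls = classify_apobec_motif(genome, "c", 5, context[2], "T")
    assert cls.is_tcw is expect_tcw
    assert cls.tetramer_class == expect_class


def test_motif_classification_minus_strand():
    # plus-strand TGAG with mutated G is the reverse complement of CTCA
    genome = _genome("AA" + revcomp("CTCA") + "AA")
    cls = classify_apobec_motif(genome, "c", 4, "G", "A")
    assert cls.tetramer_class == "YTCA"


def test_ams_is_one_on_pure_tca_repeat():
    """Interior mutations on a TCA-repeat genome: the mutated-C fraction
    in TCW equals the context fraction exactly, so AMS = 1."""
    genome = _genome("TCA" * 40)
    records = [
        MutationRecord("S1", "c", pos, "C", "T")
        for pos in range(2, 121, 3)
        if 21 <= pos <= 100  # windows fully interior
    ]
    (result,) = compute_ams(records, genome)
    assert result.ams == pytest.approx(1.0)
    assert result.n_mut_tcw == result.n_mut_c


def _brute_force_ams(seq: str, records, window: int = 20) -> tuple[int, int, int, int]:
    """Independent oracle: slice each mutation's window and regex-match
    the trinucleotide around every C/G base inside it."""
    mut_tcw = mut_c = ctx_tcw = ctx_c = 0
    for rec in records:
        i = rec.pos - 1
        tri = seq[i - 1 : i + 2]
        in_tcw = (
            re.fullmatch("TC[AT]", tri) if seq[i] == "C" else re.fullmatch("[AT]GA", tri)
        ) is not None
        for j in range(max(0, i - window), min(len(seq), i + window + 1)):
            if abs(j - i) <= 1 or seq[j] not in "CG":
                continue
            ctx_c += 1
            around = seq[max(0, j - 1) : j + 2]
            pat = "TC[AT]" if seq[j] == "C" else "[AT]GA"
            ctx_tcw += re.fullmatch(pat, around) is not None
        mut_c += 1
        mut_tcw += in_tcw
    return mut_tcw, mut_c, ctx_tcw, ctx_c


def test_ams_matches_brute_force_on_shipped_fixture(ams_records, toy_seq, toy_genome):
    (result,) = compute_ams(ams_records, toy_genome)
    mt, mc, ct, cc = _brute_force_ams(toy_seq, ams_records)
    assert (result.n_mut_tcw, result.n_mut_c) == (mt, mc)
    assert (result.n_ctx_tcw, result.n_ctx_c) == (ct, cc)
    assert result.ams == pytest.approx((mt / mc) / (ct / cc))


def test_ams_matches_brute_force_on_random_cohort():
    genome = gen_reference(30_000, seed=4)
    sigs = synthetic_signature_catalog(8)
    records, _ = gen_cohort_mutations(genome, 2, sigs, mean_mutations=150, seed=5)
    seq = genome.contigs["chrS"]
    for res in compute_ams(records, genome):
        sample_recs = [
            r for r in records if r.sample == res.sample and seq[r.pos - 1] in "CG"
            and (r.alt in "TG" if seq[r.pos - 1] == "C" else r.alt in "AC")
        ]
        mt, mc, ct, cc = _brute_force_ams(seq, sample_recs)
        assert (res.n_mut_tcw, res.n_mut_c, res.n_ctx_tcw, res.n_ctx_c) == (mt, mc, ct, cc)


def test_ams_undefined_flagged_not_fatal():
    genome = _genome("AAACAAAA" * 4)
    # C>A is not an eligible substitution under the default C>T/C>G rule
    records = [MutationRecord("S1", "c", 4, "C", "A")]
    (result,) = compute_ams(records, genome)
    assert np.isnan(result.ams) and not result.defined
    (all_subs,) = compute_ams(records, genome, subs="all")
    assert all_subs.n_mut_c == 1


def test_ams_increases_with_apobec_weight():
    """Mean AMS is monotone in the APOBEC signature weight (3-point grid)."""
    genome = gen_reference(60_000, seed=10)
    sigs = synthetic_signature_catalog(8)
    apo = [sigs.names.index("APOBEC-A"), sigs.names.index("APOBEC-B")]
    means = []
    for k, w_apo in enumerate((0.05, 0.45, 0.9)):
        def sampler(rng, w_apo=w_apo):
            w = np.full(8, (1 - w_apo) / 6)
            for j in apo:
                w[j] = w_apo / 2
            return w

        records, _ = gen_cohort_mutations(
            genome, 12, sigs, mean_mutations=120, weight_sampler=sampler, seed=11 + k
        )
        results = compute_ams(records, genome)
        means.append(np.mean([r.ams for r in results if r.defined]))
    assert means[0] < means[1] < means[2]


def test_strand_symmetry_of_ams_and_motifs():
    genome = gen_reference(20_000, seed=12)
    sigs = synthetic_signature_catalog(8)
    records, _ = gen_cohort_mutations(genome, 3, sigs, mean_mutations=100, seed=13)
    L = genome.length("chrS")
    comp = dict(zip("ACGT", "TGCA"))
    flipped = [
        MutationRecord(r.sample, r.chrom, L - r.pos + 1, comp[r.ref], comp[r.alt])
        for r in records
    ]
    genome_rc = genome.reverse_complemented()
    for a, b in zip(compute_ams(records, genome), compute_ams(flipped, genome_rc)):
        assert (a.n_mut_tcw, a.n_mut_c, a.n_ctx_tcw, a.n_ctx_c) == (
            b.n_mut_tcw, b.n_mut_c, b.n_ctx_tcw, b.n_ctx_c,
        )
    for a, b in zip(ytca_rtca_counts(records, genome), ytca_rtca_counts(flipped, genome_rc)):
        assert (a.ytca, a.rtca, a.ytcw, a.rtcw) == (b.ytca, b.rtca, b.ytcw, b.rtcw)


def test_ytca_rtca_ratio_on_planted_motifs():
    """70 YTCA + 30 RTCA planted events give the 7:3 count ratio."""
    seq = "CTCAGG" * 70 + "ATCAGG" * 30
    genome = _genome(seq)
    records = [
        MutationRecord("S1", "c", 6 * i + 3, "C", "T") for i in range(100)
    ]
    (counts,) = ytca_rtca_counts(records, genome)
    assert (counts.ytca, counts.rtca) == (70, 30)
    assert counts.ratio_ytca_rtca == pytest.approx(7 / 3)
    table = motif_table([counts])
    assert table.loc["TOTAL", "ytca"] == 70


def test_motif_counts_empty_and_invariants(toy_genome, ams_records):
    (counts,) = ytca_rtca_counts(ams_records, toy_genome)
    assert counts.ytcw >= counts.ytca and counts.rtcw >= counts.rtca
    no_tcw = [MutationRecord("S1", "toy", 35, "C", "G")]  # ACA context
    (zero,) = ytca_rtca_counts(no_tcw, toy_genome)
    assert (zero.ytca, zero.rtca, zero.ytcw, zero.rtcw) == (0, 0, 0, 0)
    assert np.isnan(zero.ratio_ytca_rtca)
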