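"""APOBEC mutagenesis enrichment score (AMS) and motif attribution.

APOBEC3 deaminases mutate cytosines in TCW motifs (W = A or T; WGA on
the opposite strand). The enrichment score for a sample is

    AMS = (mut_TCW / mut_C) / (ctx_TCW / ctx_C)

where ``mut_TCW`` counts eligible mutated cytosines falling in TCW,
``mut_C`` all eligible mutated cytosines, and ``ctx_TCW`` / ``ctx_C``
the TCW-or-WGA motifs and C-or-G bases found inside the 41-nucleotide
window (+/-20 nt) centered on each eligible mutation, summed over
mutations (overlapping windows count their content repeatedly, one
window per mutation). AMS > 1 indicates APOBEC-driven enrichment.

The tetranucleotide refinement splits TCA mutations by the base 5' of
the TCA: a pyrimidine (YTCA) marks the APOBEC3A-like preference, a
purine (RTCA) the APOBEC3B-like preference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import PURINES, PYRIMIDINES, revcomp
from .io_catalog import ContextUnavailable, GenomeSequence, MutationRecord

#: mutated-C alt alleles eligible for AMS by default (C>T and C>G, the
#: deamination outcomes); pass ``subs="all"`` to count every C mutation.
DEFAULT_SUBS: tuple[str, ...] = ("T", "G")


@dataclass(frozen=True)
class MotifClass:
    is_tcw: bool
    tetramer_class: str  # YTCA | RTCA | YTCW_nonA | RTCW_nonA | none

    @property
    def is_ytcw(self) -> bool:
        return self.tetramer_class in {"YTCA", "YTCW_nonA"}

    @property
    def is_rtcw(self) -> bool:
        return self.tetramer_class in {"RTCA", "RTCW_nonA"}


@dataclass(frozen=True)
class AMSResult:
    sample: str
    n_mut_tcw: int
    n_mut_c: int
    n_ctx_tcw: int
    n_ctx_c: int
    ams: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return not np.isnan(self.ams)


def _normalized_context(
    genome: GenomeSequence, chrom: str, pos: int, ref: str, alt: str
) -> tuple[str, str]:
    """(4-mer at offsets -2..+1 on the pyrimidine strand, normalized alt).

    For a mutated purine the plus-strand window [pos-1, pos+2] is
    reverse-complemented so the mutated base always sits at index 2.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if genome.base(chrom, pos) != ref:
        raise ContextUnavailable(f"ref mismatch at {chrom}:{pos}", "ref_mismatch")
    if ref in PURINES:
        # offsets -1..+2 on plus strand become -2..+1 after revcomp
        if pos + 2 > genome.length(chrom) or pos - 1 < 1:
            raise ContextUnavailable(f"{chrom}:{pos} at contig edge", "contig_edge")
        tet = revcomp(genome.slice(chrom, pos - 2, pos + 2))
        alt = revcomp(alt)
    else:
        if pos - 3 < 0 or pos + 1 > genome.length(chrom):
            raise ContextUnavailable(f"{chrom}:{pos} at contig edge", "contig_edge")
        tet = genome.slice(chrom, pos - 3, pos + 1)
    if any(b not in "ACGT" for b in tet):
        raise ContextUnavailable(f"N in context at {chrom}:{pos}", "n_context")
    return tet, alt


def classify_apobec_motif(
    genome: GenomeSequence, chrom: str, pos: int, ref: str, alt: str
) -> MotifClass:
    """Classify a mutated C/G into TCW and YTCA/RTCA tetramer classes.

    The context is pyrimidine-normalized first, so a G>A on the plus
    strand is scored as its C>T image on the minus strand.
    """
    tet, _ = _normalized_context(genome, chrom, pos, ref, alt)
    minus2, minus1, center, plus1 = tet
    if center != "C" or minus1 != "T" or plus1 not in "AT":
        return MotifClass(is_tcw=False, tetramer_class="none")
    yr = "Y" if minus2 in PYRIMIDINES else "R"
    cls = f"{yr}TCA" if plus1 == "A" else f"{yr}TCW_nonA"
    return MotifClass(is_tcw=True, tetramer_class=cls)


def _eligible(
    genome: GenomeSequence, rec: MutationRecord, subs: Sequence[str] | str
) -> bool:
    """Eligible = SNV at a C (or G) whose normalized alt is in ``subs``."""
    if not rec.is_snv:
        return False
    try:
        ref = genome.base(rec.chrom, rec.pos)
    except (IndexError, KeyError):
        return False
    if ref != rec.ref or ref not in "CG":
        return False
    if subs == "all":
        return rec.alt in "ACGT"
    alt = rec.alt if ref == "C" else revcomp(rec.alt)
    return alt in subs


def _window_counts(genome: GenomeSequence, chrom: str, pos: int, window: int) -> tuple[int, int]:
    """(TCW/WGA motif count, C+G base count) in the +/-window nt region.

    A motif counts when its mutable base (the C of TCW or the G of WGA)
    lies inside the window; the one-base flanks may extend past the
    window edge (they are read from the genome). The central
    trinucleotide (the mutated base and its two neighbors) is excluded
    from both counts: the center is C/G by construction and its
    neighbors can never head a motif (their flank is the mutated base),
    so including them would systematically understate the background
    motif fraction and inflate the score ~5% even for uniformly placed
    mutations. With the exclusion, uniform placement over cytosines has
    expected enrichment exactly 1. The window is truncated at contig
    ends; N bases contribute to neither count.
    """
    cg_prefix, tcw_prefix = _motif_prefix_sums(genome, chrom)
    n = len(genome.contigs[chrom])
    lo = max(pos - window, 1)
    hi = min(pos + window, n)
    cg = int(cg_prefix[hi] - cg_prefix[lo - 1])
    tcw = int(tcw_prefix[hi] - tcw_prefix[lo - 1])
    ex_lo, ex_hi = max(pos - 1, lo), min(pos + 1, hi)
    cg -= int(cg_prefix[ex_hi] - cg_prefix[ex_lo - 1])
    tcw -= int(tcw_prefix[ex_hi] - tcw_prefix[ex_lo - 1])
    return tcw, cg


def _motif_prefix_sums(genome: GenomeSequence, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Cached cumulative counts of C/G bases and TCW/WGA mutable-base
    positions along a contig (index i = count over positions 1..i)."""
    cache = getattr(genome, "_motif_prefix_cache", None)
    if cache is None:
        cache = {}
        genome._motif_prefix_cache = cache  # type: ignore[attr-defined]
    if chrom not in cache:
        arr = np.frombuffer(genome.contigs[chrom].encode("ascii"), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        is_t = arr == b"T"
        is_w = (arr == b"A") | is_t
        cg = is_c | is_g
        motif = np.zeros(arr.shape, dtype=bool)
        # C of TCW on the plus strand; G of WGA (minus-strand TCW image)
        motif[1:-1] |= is_c[1:-1] & is_t[:-2] & is_w[2:]
        motif[1:-1] |= is_g[1:-1] & is_w[:-2] & (arr[2:] == b"A")
        cache[chrom] = (
            np.concatenate([[0], np.cumsum(cg)]),
            np.concatenate([[0], np.cumsum(motif)]),
        )
    return cache[chrom]


def compute_ams(
    records: Iterable[MutationRecord],
    genome: GenomeSequence,
    window: int = 20,
    subs: Sequence[str] | str = DEFAULT_SUBS,
) -> list[AMSResult]:
    """Per-sample APOBEC enrichment scores.

    ``window`` is the half-width of the context region (default 20,
    i.e. 41 nt centered on the mutation). ``subs`` selects eligible
    substitutions of the normalized mutated C ("all" or alt alleles,
    default C>T and C>G).

    Samples whose denominators vanish get ``ams = NaN`` (flagged, run
    continues).
    """
    acc: dict[str, list[int]] = {}
    for rec in records:
        bucket = acc.setdefault(rec.sample, [0, 0, 0, 0])
        if not _eligible(genome, rec, subs):
            continue
        try:
            motif = classify_apobec_motif(genome, rec.chrom, rec.pos, rec.ref, rec.alt)
        except ContextUnavailable:
            continue
        ctx_tcw, ctx_c = _window_counts(genome, rec.chrom, rec.pos, window)
        bucket[0] += int(motif.is_tcw)
        bucket[1] += 1
        bucket[2] += ctx_tcw
        bucket[3] += ctx_c
    out = []
    for sample, (mt, mc, ct, cc) in acc.items():
        if mc > 0 and ct > 0 and cc > 0:
            ams = (mt / mc) / (ct / cc)
        else:
            ams = float("nan")
        out.append(AMSResult(sample, mt, mc, ct, cc, ams))
    return out


def ams_table(results: Sequence[AMSResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("sample")


@dataclass(frozen=True)
class MotifCounts:
    sample: str
    ytca: int
    rtca: int
    ytcw: int
    rtcw: int

    @property
    def ratio_ytca_rtca(self) -> float:
        return self.ytca / self.rtca if self.rtca else float("inf") if self.ytca else float("nan")

    @property
    def ratio_ytcw_rtcw(self) -> float:
        return self.ytcw / self.rtcw if self.rtcw else float("inf") if self.ytcw else float("nan")


def ytca_rtca_counts(
    records: Iterable[MutationRecord],
    genome: GenomeSequence,
    subs: Sequence[str] | str = DEFAULT_SUBS,
) -> list[MotifCounts]:
    """Per-sample YTCA/RTCA (and YTCW/RTCW) event counts among eligible
    mutations; sum rows for cohort totals."""
    acc: dict[str, list[int]] = {}
    for rec in records:
        bucket = acc.setdefault(rec.sample, [0, 0, 0, 0])
        if not _eligible(genome, rec, subs):
            continue
        try:
            motif = classify_apobec_motif(genome, rec.chrom, rec.pos, rec.ref, rec.alt)
        except ContextUnavailable:
            continue
        if motif.tetramer_class == "YTCA":
            bucket[0] += 1
        elif motif.tetramer_class == "RTCA":
            bucket[1] += 1
        if motif.is_ytcw:
            bucket[2] += 1
        elif motif.is_rtcw:
            bucket[3] += 1
    return [MotifCounts(s, *vals) for s, vals in acc.items()]


def motif_table(counts: Sequence[MotifCounts], with_total: bool = True) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "sample": c.sample,
                "ytca": c.ytca,
                "rtca": c.rtca,
                "ytcw": c.ytcw,
                "rtcw": c.rtcw,
                "ratio_ytca_rtca": c.ratio_ytca_rtca,
                "ratio_ytcw_rtcw": c.ratio_ytcw_rtcw,
            }
            for c in counts
        ]
    ).set_index("sample")
    if with_total and len(df):
        tot = MotifCounts(
            "TOTAL",
            int(df["ytca"].sum()),
            int(df["rtca"].sum()),
            int(df["ytcw"].sum()),
            int(df["rtcw"].sum()),
        )
        df.loc["TOTAL"] = [
            tot.ytca, tot.rtca, tot.ytcw, tot.rtcw,
            tot.ratio_ytca_rtca, tot.ratio_ytcw_rtcw,
        ]
    return df
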