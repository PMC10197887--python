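"""Variant and reference I/O, 96-channel catalogs, and mutation burden.

Coordinates are 1-based in VCF/MAF and in :class:`MutationRecord` (the
user-facing record mirrors the file formats); conversion to 0-based
half-open happens only where sequence is sliced.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS, PURINES, channel_label, revcomp

log = logging.getLogger(__name__)

# MAF Variant_Classification values counted as protein-altering.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)
SYNONYMOUS_CLASSES = frozenset({"Silent"})


class ContextUnavailable(ValueError):
    """Raised when a trinucleotide context cannot be resolved (N base or
    contig edge); callers exclude the record rather than abort."""

    def __init__(self, message: str, reason: str = "context"):
        super().__init__(message)
        self.reason = reason


@dataclass
class GenomeSequence:
    """Reference sequence held in memory as uppercase contig strings."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def length(self, chrom: str) -> int:
        return len(self.contigs[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        seq = self.contigs[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside {chrom} [1, {len(seq)}]")
        return seq[pos - 1]

    def slice(self, chrom: str, start0: int, end0: int, truncate: bool = False) -> str:
        """Sequence on [start0, end0) 0-based; optionally truncated at edges."""
        seq = self.contigs[chrom]
        if truncate:
            start0, end0 = max(start0, 0), min(end0, len(seq))
        if start0 < 0 or end0 > len(seq):
            raise IndexError(f"[{start0}, {end0}) outside {chrom} of length {len(seq)}")
        return seq[start0:end0]

    def reverse_complemented(self) -> "GenomeSequence":
        return GenomeSequence({c: revcomp(s) for c, s in self.contigs.items()})


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant of one sample (1-based position, VCF-style alleles)."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = "SNV"  # "SNV" | "indel"
    effect: str = "unknown"  # nonsynonymous | synonymous | other | unknown
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(
                f"no-op variant at {self.chrom}:{self.pos} ({self.ref}>{self.alt})"
            )
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if is_snv != (self.variant_class == "SNV"):
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"


@dataclass
class MutationCatalog:
    """Samples x 96 substitution counts in the fixed channel order."""

    counts: pd.DataFrame  # index = samples, columns = CHANNELS
    excluded: dict[str, Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CHANNELS:
            self.counts = self.counts.reindex(columns=list(CHANNELS), fill_value=0)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("catalog counts must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(df.astype(int))


@dataclass(frozen=True)
class SampleBurden:
    sample: str
    n_nonsyn_snv: int
    n_indel: int
    target_mb: float
    tmb: float


def _effect_from_maf(classification: str) -> str:
    if classification in NONSYNONYMOUS_CLASSES:
        return "nonsynonymous"
    if classification in SYNONYMOUS_CLASSES:
        return "synonymous"
    return "other"


def read_variants(
    path: str | Path,
    format: str | None = None,
    sample: str | None = None,
    sample_map: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Read somatic variants from a VCF (4.x, plain or bgzipped) or MAF.

    For VCF input the sample identifier is taken from ``sample`` (one
    sample for the whole file), or from the file's single genotype
    column; ``sample_map`` renames genotype-column names. MAF rows carry
    their own Tumor_Sample_Barcode.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        format = "maf" if name.endswith((".maf", ".maf.txt", ".maf.gz")) else "vcf"
    if format == "vcf":
        return _read_vcf(path, sample=sample, sample_map=sample_map)
    if format == "maf":
        return _read_maf(path)
    raise ValueError(f"unknown variant format {format!r}")


def _read_vcf(
    path: Path, sample: str | None, sample_map: Mapping[str, str] | None
) -> list[MutationRecord]:
    import pysam

    records: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        if sample is None:
            if len(vcf_samples) == 1:
                sample = vcf_samples[0]
                if sample_map:
                    sample = sample_map.get(sample, sample)
            elif len(vcf_samples) == 0:
                raise ValueError(
                    f"{path}: VCF has no sample column; pass sample= explicitly"
                )
        for rec in vf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt is None or alt in {".", "*"} or alt.startswith("<"):
                    continue
                try:
                    vclass = "SNV" if len(rec.ref) == 1 and len(alt) == 1 else "indel"
                    records.append(
                        MutationRecord(
                            sample=sample if sample is not None else vcf_samples[0],
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            variant_class=vclass,
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}: bad variant at line for "
                                     f"{rec.chrom}:{rec.pos}: {exc}") from exc
    return records


_MAF_REQUIRED = [
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
]


def _read_maf(path: Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: MAF missing required columns {missing}")
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        ref, alt = d["Reference_Allele"], d["Tumor_Seq_Allele2"]
        vtype = d.get("Variant_Type", "")
        if vtype in {"INS", "DEL"} or "-" in (ref, alt) or len(ref) != len(alt):
            vclass = "indel"
            ref = ref.replace("-", "")
            alt = alt.replace("-", "")
            if ref == alt:  # can't represent; keep distinguishable
                alt = alt + "N" if alt else "N"
        elif len(ref) == 1 and len(alt) == 1:
            vclass = "SNV"
        else:
            vclass = "indel"
        effect = _effect_from_maf(d.get("Variant_Classification", ""))
        try:
            records.append(
                MutationRecord(
                    sample=d["Tumor_Sample_Barcode"],
                    chrom=d["Chromosome"],
                    pos=int(d["Start_Position"]),
                    ref=ref,
                    alt=alt,
                    variant_class=vclass,
                    effect=effect,
                    gene=d.get("Hugo_Symbol") or None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as a minimal MAF (the columns this package reads)."""
    rows = []
    for r in records:
        if r.variant_class == "SNV":
            vtype = "SNP"
        else:
            vtype = "DEL" if len(r.ref) > len(r.alt) else "INS"
        rows.append(
            {
                "Hugo_Symbol": r.gene or "Unknown",
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref,
                "Tumor_Seq_Allele2": r.alt,
                "Variant_Classification": {
                    "nonsynonymous": "Missense_Mutation",
                    "synonymous": "Silent",
                }.get(r.effect, "IGR"),
                "Variant_Type": vtype,
                "Tumor_Sample_Barcode": r.sample,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def trinucleotide_context(
    genome: GenomeSequence, chrom: str, pos: int, ref: str, alt: str
) -> str:
    """Pyrimidine-normalized channel label of an SNV, e.g. ``"T[C>T]A"``.

    Raises :class:`ContextUnavailable` when the position sits at a
    contig edge or any of ref/alt/flanks is not an unambiguous base.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if pos <= 1 or pos >= genome.length(chrom):
        raise ContextUnavailable(f"{chrom}:{pos} lacks a flanking base", "contig_edge")
    genome_ref = genome.base(chrom, pos)
    if genome_ref != ref:
        raise ContextUnavailable(
            f"reference mismatch at {chrom}:{pos}: genome has {genome_ref}, variant {ref}",
            "ref_mismatch",
        )
    tri = genome.slice(chrom, pos - 2, pos + 1)
    if any(b not in "ACGT" for b in tri) or alt not in "ACGT":
        raise ContextUnavailable(
            f"ambiguous base in context {tri} at {chrom}:{pos}", "n_context"
        )
    return channel_label(tri[0], ref, alt, tri[2])


def build_catalog(
    records: Iterable[MutationRecord], genome: GenomeSequence
) -> MutationCatalog:
    """Count classifiable SNVs per sample into the 96 channels.

    Non-SNVs are skipped silently (they are not substitutions); SNVs
    with unresolvable context are excluded and tallied per sample in
    ``catalog.excluded``.
    """
    counts: dict[str, np.ndarray] = {}
    excluded: dict[str, Counter] = {}
    n_classified = 0
    order = {c: i for i, c in enumerate(CHANNELS)}
    for rec in records:
        row = counts.setdefault(rec.sample, np.zeros(96, dtype=np.int64))
        if not rec.is_snv:
            continue
        try:
            label = trinucleotide_context(genome, rec.chrom, rec.pos, rec.ref, rec.alt)
        except ContextUnavailable as exc:
            excluded.setdefault(rec.sample, Counter())[exc.reason] += 1
            log.warning("excluding %s:%d (%s)", rec.chrom, rec.pos, exc)
            continue
        row[order[label]] += 1
        n_classified += 1
    if n_classified == 0:
        raise ValueError("no classifiable SNVs in input")
    df = pd.DataFrame.from_dict(counts, orient="index", columns=list(CHANNELS))
    df.index.name = "sample"
    return MutationCatalog(df, excluded=excluded)


def compute_tmb(
    records: Iterable[MutationRecord],
    target_mb: float = 38.0,
    include_unknown: bool = False,
) -> list[SampleBurden]:
    """Tumor mutation burden: nonsynonymous SNVs plus indels per megabase.

    ``include_unknown`` additionally counts SNVs lacking an effect
    annotation in the numerator.
    """
    if target_mb <= 0:
        raise ValueError(f"target_mb must be positive, got {target_mb}")
    nonsyn: Counter = Counter()
    indel: Counter = Counter()
    samples: list[str] = []
    for rec in records:
        if rec.sample not in nonsyn:
            samples.append(rec.sample)
            nonsyn[rec.sample] = 0
            indel[rec.sample] = 0
        if rec.variant_class == "indel":
            indel[rec.sample] += 1
        elif rec.effect == "nonsynonymous" or (include_unknown and rec.effect == "unknown"):
            nonsyn[rec.sample] += 1
    return [
        SampleBurden(
            sample=s,
            n_nonsyn_snv=nonsyn[s],
            n_indel=indel[s],
            target_mb=target_mb,
            tmb=(nonsyn[s] + indel[s]) / target_mb,
        )
        for s in samples
    ]


def burden_table(burdens: Sequence[SampleBurden]) -> pd.DataFrame:
    df = pd.DataFrame([b.__dict__ for b in burdens]).set_index("sample")
    return df


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write contigs to FASTA and build a .fai index alongside."""
    import pyfaidx

    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pyfaidx.Faidx(str(path))
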