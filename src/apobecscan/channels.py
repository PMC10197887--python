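"""The 96-channel single-base-substitution alphabet.

Somatic SNVs are summarized on the pyrimidine strand: a mutation whose
reference base is a purine is reverse-complemented together with its
flanks, so every channel has a C or T reference. Channels are ordered
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), each with the 16
5'/3' flank combinations in A,C,G,T order.
"""

from __future__ import annotations

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}

#: Channels attributed to APOBEC deamination: mutated C in a TCW motif
#: changed to T or G (W = A or T).
APOBEC_CHANNELS: tuple[str, ...] = tuple(
    f"T[C>{alt}]{w}" for alt in "TG" for w in "AT"
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def channel_label(fivep: str, ref: str, alt: str, threep: str) -> str:
    """Build a pyrimidine-normalized channel label from raw strand context.

    If ``ref`` is a purine, all four bases are complemented and the
    flanks swap sides.
    """
    if ref in PURINES:
        fivep, ref, alt, threep = revcomp(threep), revcomp(ref), revcomp(alt), revcomp(fivep)
    label = f"{fivep}[{ref}>{alt}]{threep}"
    if label not in CHANNEL_INDEX:
        raise ValueError(f"not a valid substitution channel: {label!r}")
    return label


def parse_channel(label: str) -> tuple[str, str, str, str]:
    """Split ``"T[C>T]A"`` into (5' flank, ref, alt, 3' flank)."""
    if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
        raise ValueError(f"malformed channel label: {label!r}")
    return label[0], label[2], label[4], label[6]
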