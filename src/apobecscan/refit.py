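"""Mutational-signature activity refitting by nonnegative least squares.

Given per-sample 96-channel counts and a reference signature catalog
(column-stochastic 96 x S profile matrix), each sample's counts are
decomposed as ``counts ~ profiles @ activities`` with activities >= 0,
so an activity is the estimated number of mutations attributed to a
signature. Signatures whose cohort-wide activity share falls below a
pruning threshold are removed and the fit repeated to a fixed point,
mirroring cohort-level signature reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .channels import CHANNELS
from .io_catalog import MutationCatalog


@dataclass
class SignatureCatalog:
    """Reference signatures: 96 x S column-stochastic profile matrix."""

    profiles: pd.DataFrame  # index = CHANNELS, columns = signature names

    def __post_init__(self) -> None:
        df = self.profiles
        unknown = set(df.index) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown context labels: {sorted(unknown)[:5]}")
        if len(df) != 96:
            raise ValueError(f"expected 96 context rows, got {len(df)}")
        df = df.reindex(list(CHANNELS))
        if (df.to_numpy() < 0).any():
            raise ValueError("signature profiles must be nonnegative")
        sums = df.sum(axis=0)
        off = (sums - 1.0).abs()
        if (off > 1e-3).any():
            bad = sums[off > 1e-3]
            raise ValueError(
                f"signature columns must sum to 1 (renormalizable within 1e-3); "
                f"got {dict(bad.round(4))}"
            )
        self.profiles = df / sums

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        return SignatureCatalog(self.profiles[list(names)].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="Type")


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-v3-layout TSV (``Type`` column of labels like
    ``A[C>A]A``, one column per signature); rows may be in any order."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "Type"
    return SignatureCatalog(df.astype(float))


@dataclass
class ActivityMatrix:
    """Samples x retained signatures activity estimates from refitting."""

    activities: pd.DataFrame  # index = samples, columns = retained signatures
    residual_norm: pd.Series  # per-sample L2 residual
    pruned: set[str] = field(default_factory=set)

    def total_by_signature(self) -> pd.Series:
        return self.activities.sum(axis=0)


def _nnls_fit(P: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    acts = np.zeros((counts.shape[0], P.shape[1]))
    resid = np.zeros(counts.shape[0])
    for i, row in enumerate(counts):
        if row.sum() == 0:
            continue
        acts[i], resid[i] = nnls(P, row.astype(float))
    return acts, resid


def refit_activities(
    catalog: MutationCatalog,
    signatures: SignatureCatalog,
    prune_frac: float = 0.01,
) -> ActivityMatrix:
    """Per-sample NNLS refit with iterative cohort-level pruning.

    Signatures with cohort activity share < ``prune_frac`` are dropped
    and the remaining set refit, repeating until stable. Deterministic
    given inputs. All-zero samples get zero activities (warned).
    """
    counts = catalog.counts.to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("catalog has no mutations")
    if (counts.sum(axis=1) == 0).any():
        import warnings

        zero = list(catalog.counts.index[counts.sum(axis=1) == 0])
        warnings.warn(f"samples with zero mutations get zero activities: {zero[:5]}")
    retained = list(signatures.names)
    pruned: set[str] = set()
    while True:
        P = signatures.profiles[retained].to_numpy()
        acts, resid = _nnls_fit(P, counts)
        shares = acts.sum(axis=0)
        total = shares.sum()
        if total == 0:
            break
        drop = [s for s, v in zip(retained, shares) if v / total < prune_frac]
        if not drop or len(drop) == len(retained):
            break
        pruned.update(drop)
        retained = [s for s in retained if s not in drop]
    activities = pd.DataFrame(acts, index=catalog.counts.index, columns=retained)
    residual = pd.Series(resid, index=catalog.counts.index, name="residual_norm")
    return ActivityMatrix(activities, residual, pruned)


def etiology_fractions(
    activities: ActivityMatrix, groups: Mapping[str, Sequence[str]]
) -> pd.Series:
    """Percent of cohort-summed activity per etiology group.

    ``groups`` maps a label (e.g. ``"APOBEC"``) to signature names;
    retained signatures not covered by any group are pooled as
    ``"Others"``. Percentages sum to 100.
    """
    if not groups:
        raise ValueError("empty group map")
    totals = activities.total_by_signature()
    missing = [s for sigs in groups.values() for s in sigs if s not in totals.index]
    if missing:
        raise KeyError(f"grouped signatures absent from activities: {missing}")
    grand = totals.sum()
    if grand == 0:
        raise ValueError("total activity is zero")
    out: dict[str, float] = {}
    covered: set[str] = set()
    for label, sigs in groups.items():
        out[label] = 100.0 * totals[list(sigs)].sum() / grand
        covered.update(sigs)
    rest = [s for s in totals.index if s not in covered]
    if rest:
        out["Others"] = 100.0 * totals[rest].sum() / grand
    return pd.Series(out, name="percent")
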