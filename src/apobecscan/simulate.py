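"""Seeded generators for synthetic cohorts with the statistical
structure the analysis modules assume.

Each generator takes an explicit seed, draws from a single local
pseudo-random stream (no global state), and returns a
:class:`TruthBundle` recording the planted parameters so recovery tests
can close the loop. The signature fixture catalogs produced here are
synthetic: two APOBEC-analog profiles concentrate their mass on the
T[C>T]W / T[C>G]W deamination channels, the remaining profiles are
sparse random draws; they imitate the *shape* of reference signature
catalogs, not any published signature's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import APOBEC_CHANNELS, CHANNELS, PYRIMIDINES, parse_channel, revcomp
from .io_catalog import GenomeSequence, MutationCatalog, MutationRecord
from .refit import SignatureCatalog

# ---------------------------------------------------------------------------
# truth serialization


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _write_toml_section(fh, table: Mapping, prefix: str = "") -> None:
    scalars = {k: v for k, v in table.items() if not isinstance(v, Mapping)}
    subtables = {k: v for k, v in table.items() if isinstance(v, Mapping)}
    if prefix and scalars:
        fh.write(f"[{prefix}]\n")
    for k, v in scalars.items():
        fh.write(f"{k} = {_toml_scalar(v)}\n")
    for k, v in subtables.items():
        fh.write("\n")
        _write_toml_section(fh, v, f"{prefix}.{k}" if prefix else k)


@dataclass
class TruthBundle:
    """Planted parameters of one generator invocation."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_toml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"generator = {_toml_scalar(self.generator)}\n")
            fh.write(f"seed = {self.seed}\n\n")
            _write_toml_section(fh, self.params, "params")

    @classmethod
    def from_toml(cls, path: str | Path) -> "TruthBundle":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(data["generator"], data["seed"], data.get("params", {}))


# ---------------------------------------------------------------------------
# reference sequence


def gen_reference(
    length: int, gc_fraction: float = 0.42, seed: int = 0, contig: str = "chrS"
) -> GenomeSequence:
    """Single-contig i.i.d. reference at the stated GC content."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0 <= gc_fraction <= 1:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return GenomeSequence({contig: seq})


# ---------------------------------------------------------------------------
# signature fixtures

FIXTURE_SIGNATURE_NAMES = (
    "AGE-A", "AGE-B", "APOBEC-A", "APOBEC-B", "SMOKE", "MMR", "POLE", "ALCOHOL",
)
APOBEC_ANALOGS = ("APOBEC-A", "APOBEC-B")

_FIXTURE_SEED = 20240901  # fixed so the fixture catalog is stable


def synthetic_signature_catalog(n_signatures: int = 8) -> SignatureCatalog:
    """Deterministic synthetic reference catalog (up to 30 signatures).

    The first eight signatures carry etiology-style names; the two
    APOBEC analogs put 80% of their mass on T[C>T]W (APOBEC-A) and
    T[C>G]W (APOBEC-B). Signatures beyond eight are named BG09..BG30.
    """
    if not 1 <= n_signatures <= 30:
        raise ValueError("n_signatures must be in [1, 30]")
    rng = np.random.default_rng(_FIXTURE_SEED)
    names = list(FIXTURE_SIGNATURE_NAMES) + [f"BG{i:02d}" for i in range(9, 31)]
    cols = {}
    idx = {c: i for i, c in enumerate(CHANNELS)}
    for name in names:  # always draw all 30 so any prefix is stable
        background = rng.dirichlet(np.full(96, 0.08))
        if name == "APOBEC-A":
            prof = 0.2 * background
            prof[idx["T[C>T]A"]] += 0.45
            prof[idx["T[C>T]T"]] += 0.35
        elif name == "APOBEC-B":
            prof = 0.2 * background
            prof[idx["T[C>G]A"]] += 0.45
            prof[idx["T[C>G]T"]] += 0.35
        else:
            prof = background
        cols[name] = prof / prof.sum()
    df = pd.DataFrame(cols, index=list(CHANNELS)).iloc[:, :n_signatures]
    df.index.name = "Type"
    return SignatureCatalog(df)


# ---------------------------------------------------------------------------
# catalog cohorts (counts drawn directly from signature mixtures)


def gen_catalog_cohort(
    signatures: SignatureCatalog,
    n_samples: int = 169,
    mean_mutations: float = 500.0,
    apobec_share: float = 0.2229,
    apobec_signatures: Sequence[str] = APOBEC_ANALOGS,
    concentration: float = 20.0,
    seed: int = 0,
) -> tuple[MutationCatalog, pd.DataFrame, TruthBundle]:
    """Per-sample 96-channel catalogs from signature mixtures.

    Each sample draws a Poisson mutation total and a signature-weight
    vector whose APOBEC-analog share has mean ``apobec_share``
    (Beta-distributed with the given concentration); counts are
    multinomial over the mixed channel profile. Returns the catalog,
    the per-sample true activities, and the truth bundle.
    """
    rng = np.random.default_rng(seed)
    names = signatures.names
    apo = [s for s in names if s in set(apobec_signatures)]
    other = [s for s in names if s not in set(apobec_signatures)]
    if not apo or not other:
        raise ValueError("need both APOBEC and non-APOBEC signatures")
    P = signatures.profiles.to_numpy()
    col = {s: i for i, s in enumerate(names)}
    counts = np.zeros((n_samples, 96), dtype=np.int64)
    truth_w = np.zeros((n_samples, len(names)))
    for i in range(n_samples):
        n_mut = rng.poisson(mean_mutations)
        w_apo = rng.beta(concentration * apobec_share, concentration * (1 - apobec_share))
        w = np.zeros(len(names))
        split = rng.dirichlet(np.full(len(apo), 2.0))
        for s, f in zip(apo, split):
            w[col[s]] = w_apo * f
        rest = rng.dirichlet(np.ones(len(other)))
        for s, f in zip(other, rest):
            w[col[s]] = (1 - w_apo) * f
        p = P @ w
        counts[i] = rng.multinomial(n_mut, p / p.sum())
        truth_w[i] = n_mut * w
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    catalog = MutationCatalog(
        pd.DataFrame(counts, index=pd.Index(samples, name="sample"), columns=list(CHANNELS))
    )
    activities = pd.DataFrame(truth_w, index=catalog.counts.index, columns=names)
    planted = float(activities[apo].sum().sum() / activities.sum().sum())
    truth = TruthBundle(
        "gen_catalog_cohort",
        seed,
        {
            "n_samples": n_samples,
            "mean_mutations": mean_mutations,
            "apobec_share_target": apobec_share,
            "apobec_share_realized": planted,
            "apobec_signatures": list(apo),
        },
    )
    return catalog, activities, truth


# ---------------------------------------------------------------------------
# genome-placed mutation cohorts


def _context_index(genome: GenomeSequence):
    """Map pyrimidine-normalized trinucleotide -> two position arrays
    (preceding normalized base pyrimidine / purine).

    Positions are (contig, 1-based pos, strand_is_plus) for interior
    sites with a full -2..+2 neighborhood of unambiguous bases.
    """
    index: dict[str, dict[str, list]] = {}
    for contig, seq in genome.contigs.items():
        n = len(seq)
        for i in range(2, n - 2):  # 0-based, needs i-2..i+2
            base = seq[i]
            if base not in "ACGT":
                continue
            hood = seq[i - 2 : i + 3]
            if any(b not in "ACGT" for b in hood):
                continue
            if base in PYRIMIDINES:
                tri = seq[i - 1 : i + 2]
                prev = seq[i - 2]
                plus = True
            else:
                tri = revcomp(seq[i - 1 : i + 2])
                prev = revcomp(seq[i + 2])
                plus = False
            bucket = index.setdefault(tri, {"Y": [], "R": []})
            bucket["Y" if prev in PYRIMIDINES else "R"].append((contig, i + 1, plus))
    return index


def gen_cohort_mutations(
    genome: GenomeSequence,
    n_samples: int,
    signatures: SignatureCatalog,
    mean_mutations: float = 200.0,
    weight_sampler: Callable[[np.random.Generator], np.ndarray] | None = None,
    ytca_pyrimidine_prob: float = 0.7,
    seed: int = 0,
    max_retries: int = 10_000,
) -> tuple[list[MutationRecord], TruthBundle]:
    """Place signature-mixture mutations onto a genome.

    Per sample, a Poisson mutation total and signature weights (uniform
    Dirichlet unless ``weight_sampler`` given) pick channels from the
    mixture; each mutation lands on a uniformly chosen genome position
    whose pyrimidine-normalized trinucleotide matches the channel.
    For the APOBEC channels (mutated C in TCW) the base 5' of the TCW
    is a pyrimidine with probability ``ytca_pyrimidine_prob``, planting
    an A3A-like (YTCA-dominant) or A3B-like motif spectrum.
    """
    rng = np.random.default_rng(seed)
    index = _context_index(genome)
    for tri in index:
        for k in ("Y", "R"):
            index[tri][k] = np.array(index[tri][k], dtype=object)
    names = signatures.names
    P = signatures.profiles.to_numpy()  # 96 x S
    apobec_set = set(APOBEC_CHANNELS)
    records: list[MutationRecord] = []
    n_apo_y = n_apo_r = 0
    channel_totals = np.zeros(96, dtype=np.int64)
    for si in range(n_samples):
        sample = f"S{si + 1:03d}"
        w = weight_sampler(rng) if weight_sampler else rng.dirichlet(np.ones(len(names)))
        p = P @ np.asarray(w, dtype=float)
        p = p / p.sum()
        n_mut = rng.poisson(mean_mutations)
        draws = rng.choice(96, size=n_mut, p=p)
        for ch_idx in draws:
            label = CHANNELS[ch_idx]
            fivep, ref, alt, threep = parse_channel(label)
            tri = fivep + ref + threep
            bucket = index.get(tri)
            if bucket is None or (len(bucket["Y"]) == 0 and len(bucket["R"]) == 0):
                raise RuntimeError(f"context {tri} absent from genome")
            if label in apobec_set:
                want_y = rng.random() < ytca_pyrimidine_prob
                arr = bucket["Y" if want_y else "R"]
                retries = 0
                while len(arr) == 0:
                    retries += 1
                    if retries > max_retries:
                        raise RuntimeError(f"no position for {label} preceding-class")
                    want_y = not want_y
                    arr = bucket["Y" if want_y else "R"]
                if want_y:
                    n_apo_y += 1
                else:
                    n_apo_r += 1
            else:
                ny, nr = len(bucket["Y"]), len(bucket["R"])
                arr = bucket["Y"] if rng.random() < ny / (ny + nr) else bucket["R"]
            contig, pos, plus = arr[rng.integers(len(arr))]
            if plus:
                actual_ref, actual_alt = ref, alt
            else:
                actual_ref, actual_alt = revcomp(ref), revcomp(alt)
            channel_totals[ch_idx] += 1
            records.append(
                MutationRecord(
                    sample=sample,
                    chrom=contig,
                    pos=int(pos),
                    ref=actual_ref,
                    alt=actual_alt,
                    variant_class="SNV",
                    effect="nonsynonymous",
                )
            )
    truth = TruthBundle(
        "gen_cohort_mutations",
        seed,
        {
            "n_samples": n_samples,
            "mean_mutations": mean_mutations,
            "ytca_pyrimidine_prob": ytca_pyrimidine_prob,
            "n_apobec_y": n_apo_y,
            "n_apobec_r": n_apo_r,
            "n_mutations": len(records),
            "channel_totals": channel_totals.tolist(),
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# survival


def gen_survival(
    n: int,
    cutoff: float = 1.5,
    hr: float = 0.3,
    baseline_hazard: float = 0.05,
    censor_rate: float = 0.3,
    score_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Survival cohort with a group hazard effect above a score cutoff.

    Scores are lognormal (median 1.5 x planted-cutoff-friendly scale);
    event times are exponential with hazard ``baseline_hazard`` below
    the cutoff and ``baseline_hazard * hr`` above it; independent
    exponential censoring is tuned to the requested censored fraction.
    Covariates (age, gender, stage, smoking, drinking) are drawn
    independently of survival.
    """
    if hr <= 0:
        raise ValueError("hr must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    score = np.exp(rng.normal(np.log(cutoff), score_sigma, size=n))
    high = score > cutoff
    haz = np.where(high, baseline_hazard * hr, baseline_hazard)
    t_event = rng.exponential(1.0 / haz)
    if censor_rate > 0:
        mean_haz = haz.mean()
        hc = mean_haz * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1.0 / hc, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame(
        {
            "sample": [f"P{i + 1:03d}" for i in range(n)],
            "score": score,
            "time": time,
            "event": event,
            "age": rng.normal(60, 8, size=n).round().astype(int),
            "gender": rng.choice(["male", "female"], size=n, p=[0.7, 0.3]),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n, p=[0.15, 0.35, 0.35, 0.15]),
            "smoking": rng.choice(["yes", "no"], size=n, p=[0.6, 0.4]),
            "drinking": rng.choice(["yes", "no"], size=n, p=[0.5, 0.5]),
        }
    ).set_index("sample")
    truth = TruthBundle(
        "gen_survival",
        seed,
        {
            "n": n,
            "cutoff": cutoff,
            "hr": hr,
            "baseline_hazard": baseline_hazard,
            "censor_rate": censor_rate,
            "n_high": int(high.sum()),
            "n_events": int(event.sum()),
        },
    )
    return df, truth


# ---------------------------------------------------------------------------
# bulk expression


def gen_bulk_expression(
    score: pd.Series,
    corr_spec: Mapping[str, float],
    n_noise_genes: int = 100,
    mu: float = 2.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """TPM-like matrix with genes at planted rank correlation to a score.

    A Gaussian copula ties each specified gene to the normal scores of
    the per-sample score at the target Spearman correlation (via the
    bivariate-normal conversion rho_pearson = 2 sin(pi rho_s / 6)),
    then exponentiates onto a TPM-like scale. Noise genes are
    independent lognormal.
    """
    for g, r in corr_spec.items():
        if not -1 < r < 1:
            raise ValueError(f"target correlation for {g} must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    score = pd.Series(score).astype(float)
    n = len(score)
    from scipy.stats import norm

    z = norm.ppf((score.rank().to_numpy() - 0.5) / n)
    rows = {}
    for g, rho_s in corr_spec.items():
        rho_p = 2 * np.sin(np.pi * rho_s / 6)
        latent = rho_p * z + np.sqrt(1 - rho_p**2) * rng.normal(size=n)
        rows[g] = np.exp(mu + sigma * latent)
    for i in range(n_noise_genes):
        rows[f"NOISE{i + 1:04d}"] = np.exp(mu + sigma * rng.normal(size=n))
    expr = pd.DataFrame(rows, index=score.index).T
    truth = TruthBundle(
        "gen_bulk_expression",
        seed,
        {
            "n_samples": n,
            "n_noise_genes": n_noise_genes,
            "corr_spec": dict(corr_spec),
        },
    )
    return expr, truth


# ---------------------------------------------------------------------------
# single-cell cohorts


def gen_sc_cohort(
    groups: Mapping[str, Mapping[str, float]],
    cells_per_group: int = 1000,
    module_spec: Mapping[str, Mapping] | None = None,
    n_noise_genes: int = 50,
    qc_violation_rates: Mapping[str, float] | None = None,
    nb_dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Annotated cell table plus a cells x genes count matrix.

    ``groups`` maps group label -> cell-type probability vector
    (multinomial composition per group). ``module_spec`` maps module
    name -> ``{"genes": [...], "strength": float}``: module genes share
    a per-cell latent factor (negative-binomial counts), planting the
    co-expression a reference-gene signature should recover. A stated
    fraction of cells per QC rule gets an out-of-bounds metadata value;
    the violating cells are recorded in the truth bundle.
    """
    rng = np.random.default_rng(seed)
    for grp, comp in groups.items():
        if abs(sum(comp.values()) - 1.0) > 1e-6:
            raise ValueError(f"composition of group {grp!r} must sum to 1")
    qc_violation_rates = dict(qc_violation_rates or {})
    module_spec = dict(module_spec or {})
    meta_rows = []
    for grp, comp in sorted(groups.items()):
        types = sorted(comp)
        probs = np.array([comp[t] for t in types])
        draws = rng.choice(len(types), size=cells_per_group, p=probs)
        for j, ti in enumerate(draws):
            meta_rows.append(
                {
                    "cell": f"{grp}_C{j + 1:05d}",
                    "sample": f"{grp}_PT{j % 4 + 1}",
                    "group": grp,
                    "cell_type": types[ti],
                    "n_genes": int(rng.integers(1000, 6001)),
                    "total_counts": int(rng.integers(2000, 15001)),
                    "pct_mito": float(rng.uniform(0, 8)),
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("cell")
    n_cells = len(meta)

    violators: dict[str, list[str]] = {}
    bounds = {
        "n_genes": lambda k: rng.integers(0, 300, size=k)
        if rng.random() < 0.5
        else rng.integers(8001, 12000, size=k),
        "total_counts": lambda k: rng.integers(20001, 40000, size=k),
        "pct_mito": lambda k: rng.uniform(10.001, 50, size=k),
    }
    for rule, rate in qc_violation_rates.items():
        if rule not in bounds:
            raise ValueError(f"unknown QC rule {rule!r}")
        k = int(round(rate * n_cells))
        if k == 0:
            violators[rule] = []
            continue
        pick = rng.choice(n_cells, size=k, replace=False)
        vals = bounds[rule](k)
        col = meta.columns.get_loc(rule)
        meta.iloc[pick, col] = vals.astype(meta.dtypes[rule])
        violators[rule] = list(meta.index[np.sort(pick)])

    module_genes = [g for m in module_spec.values() for g in m["genes"]]
    genes = module_genes + [f"NOISE{i + 1:03d}" for i in range(n_noise_genes)]
    base = rng.normal(0.5, 0.3, size=len(genes))
    log_lambda = np.tile(base, (n_cells, 1))
    for m in module_spec.values():
        f = rng.normal(0, 1, size=n_cells)
        for g in m["genes"]:
            log_lambda[:, genes.index(g)] += m.get("strength", 0.8) * f
    lam = np.exp(log_lambda)
    shape = nb_dispersion
    counts = rng.poisson(rng.gamma(shape, lam / shape))
    expr = pd.DataFrame(counts, index=meta.index, columns=genes)

    truth = TruthBundle(
        "gen_sc_cohort",
        seed,
        {
            "cells_per_group": cells_per_group,
            "composition": {g: dict(c) for g, c in groups.items()},
            "modules": {
                name: {"genes": list(m["genes"]), "strength": float(m.get("strength", 0.8))}
                for name, m in module_spec.items()
            },
            "qc_violators": violators,
        },
    )
    return meta, expr, truth


def write_mtx(expr: pd.DataFrame, outdir: str | Path) -> None:
    """Write a cells x genes matrix as MatrixMarket plus barcode/feature TSVs."""
    from scipy import io as spio
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), csr_matrix(expr.to_numpy()))
    pd.Series(expr.index).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(expr.columns).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)


def read_mtx(indir: str | Path) -> pd.DataFrame:
    from scipy import io as spio

    indir = Path(indir)
    mat = spio.mmread(str(indir / "matrix.mtx")).toarray()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=cells, columns=genes)
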