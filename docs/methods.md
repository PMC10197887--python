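# Methods

This note documents the statistical procedures the package implements,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions made
where the underlying definitions were open.

## Mutation catalogs and burden

Somatic SNVs are classified into the 96 trinucleotide substitution
channels on the pyrimidine strand: when the reference base is a purine,
the ref/alt pair and both flanks are reverse-complemented, so every
channel has a C or T reference. Channel order is substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G × 16 flank pairs); signature catalogs in
COSMIC layout are re-ordered to this internal order on read, so file
row order never matters. Coordinates are 1-based at the I/O boundary
(VCF/MAF convention) and converted to 0-based half-open only where
sequence is sliced.

SNVs whose context cannot be resolved (N in a flank, contig edge,
reference mismatch) are excluded and tallied per sample, never fatal;
catalog row sums plus these exclusions conserve the input SNV count.
Indels are excluded from catalogs (they are not substitutions) but
count toward tumor mutation burden, defined as nonsynonymous SNVs plus
indels per megabase of target territory. The target size is
configuration (default 38 Mb, a typical exome footprint); variants with
unknown effect annotation enter the numerator only when
`include_unknown` is set, since burden conventions differ on this
point.

## APOBEC enrichment score

For each sample,

    AMS = (mut_TCW / mut_C) / (ctx_TCW / ctx_C)

where `mut_TCW` / `mut_C` count eligible mutated cytosines (in TCW /
total) and the context terms count, summed over one ±20 nt window per
eligible mutation, the TCW-or-WGA motifs and the C-or-G bases in that
window. Windows overlap freely and are summed with double counting —
each mutation contributes its own window. Eligibility defaults to C>T
and C>G (the deamination outcomes, following the enrichment score's
original definition); `subs="all"` admits every mutated-C substitution.

Two numerical choices make the score exactly calibrated:

1. **Motifs are counted at their mutable base.** A TCW (or WGA) motif
   counts when its C (or G) lies inside the window; the one-base flanks
   are read from the genome even when they extend past the window edge.
   Counting motifs only when fully contained in the window string would
   undercount motif starts relative to bases (39 starts vs 41 bases)
   and inflate the null score by ~5%.
2. **The central trinucleotide is excluded from the context counts.**
   The window center is a mutated C/G by construction, and its two
   neighbors can never head a motif (their flank is that C/G, not T/W),
   so including these three positions biases the background motif
   fraction downward. With both choices, mutations placed uniformly at
   random over cytosines of an i.i.d. genome have expected AMS exactly
   1 up to the O(1/m) ratio-estimator term, which the null-calibration
   test verifies empirically (cohort mean within 2 SE of 1 at 200
   samples × 500 mutations).

Windows are truncated at contig ends; N bases count in neither
numerator nor denominator. Samples with an empty denominator get a
flagged NaN score and the run continues. Both strands are always
scanned: TCW on the given strand plus WGA, its reverse-complement
image; the motifs cannot overlap palindromically, so no de-duplication
is needed.

### Motif attribution

Among eligible mutations in TCW, the base 5' of the (normalized)
trinucleotide refines the attribution: a pyrimidine (YTCA / YTCW)
marks the APOBEC3A-like preference, a purine (RTCA / RTCW) the
APOBEC3B-like one. Counts and their ratios are reported per sample and
as cohort totals; a zero denominator yields an infinite (or NaN when
both are zero) ratio, not an exception.

## Signature refitting

Per-sample activities solve `min ‖counts − P·a‖₂, a ≥ 0` (NNLS) against
a column-stochastic 96 × S reference matrix — activities are estimated
mutation counts per signature. De-novo extraction is deliberately out
of scope: attribution against a known catalog is the quantity the
downstream analyses consume. After fitting, any signature whose share
of cohort-wide activity falls below `prune_frac` (default 1%) is
dropped and the remaining set refit, iterating to a fixed point; the
criterion is cohort-level rather than per-sample to mirror cohort-level
signature reporting. The procedure is deterministic, scale-equivariant
in the noiseless case, and idempotent on its own retained set. Etiology
fractions sum grouped activities (e.g. APOBEC = the two deamination
signatures) over the cohort total, with ungrouped signatures pooled as
"Others".

The objective is least squares on raw counts; no per-sample
normalization or cosine objective is offered, keeping activities on the
mutation-count scale.

## Survival analysis

The cut-point scan considers midpoints between consecutive distinct
sorted scores whose induced groups each hold at least
`max(2, ⌈minprop·n⌉)` samples (minprop default 0.1, the cited cut-point
routine's convention; the absolute floor of 2 exists because a log-rank
test against a singleton group is untestable). The returned cutoff
minimizes the two-sided log-rank p; ties break toward the candidate
nearest the median score. An explicit fixed-increment grid can replace
the midpoint set.

Minimizing p over many correlated candidates is anti-conservative by
construction — under a null simulation the fraction of minimum-p values
below 0.05 clearly exceeds 0.05. `n_permutations > 0` therefore refers
the observed minimum to the null distribution of minima under random
relabeling of scores, and the permutation-adjusted rejection rate is
calibrated (verified within 2 SE of nominal in a scaled-down null
simulation). The scan uses an internal vectorized log-rank statistic;
it is tested to agree with lifelines' `logrank_test` to 1e-8, which
also backs the public `logrank` function. Cox models use lifelines with
Efron tie handling; categorical covariates are dummy-expanded against a
configurable reference level, and rank-deficient designs or fits with
fewer events than terms are rejected up front.

Quantile grouping labels the tails of a score (default q = 0.25, linear
interpolation quantiles, ties joining the extreme group) for contrasts
between upper and lower groups.

## Pathway mutation enrichment

Stage 1 screens each pathway's cohort-wide mutation count against a
gene-count-proportional expectation: the observed pathway/non-pathway
split is tested by two-sided Fisher against the split expected if
mutations fell on genes uniformly (pathway size / gene-universe size;
the universe defaults to the union of gene-set and mutated genes and is
configurable). Pathways with p < 0.05 and BH-FDR < 0.25 proceed — both
thresholds must hold. This stage-1 null is a declared construction of
this package: the procedure it stands in for is cited in the source
literature without enough detail to reproduce exactly, so the
construction is explicit, configurable, and logged rather than
presented as canonical. Stage 2 tests each candidate's 2×2 table of
pathway vs non-pathway mutation counts across the two sample groups
(two-sided Fisher), BH-adjusted across candidates. The two stages are
separate multiple-testing families. Pathways with zero mutations are
skipped with a log entry. Fisher p-values are verified against an
exact hypergeometric enumeration oracle, and the BH step against a
textbook step-up implementation.

## Expression and single-cell scores

CYT is `sqrt((PRF1 + δ)(GZMA + δ))` per sample with pseudo-abundance
δ = 0.01 by default (the common convention; δ = 0 is allowed when all
values are positive). Score-gene correlation defaults to Spearman
everywhere, computed on ranks with a vectorized Pearson kernel; the
ranking is invariant to monotone transforms of the score. Gene-set
scores average log1p-then-z-scored expression over the present genes
(constant genes contribute 0; missing genes are dropped with a warning
naming them) — the aggregation is the package's choice, stated because
the underlying convention varies between studies.

Single-cell QC keeps cells with genes detected in [300, 8000], total
counts ≤ 20000 and mitochondrial percentage ≤ 10, all bounds inclusive
(the range endpoints are ambiguous in prose; inclusive was chosen and
is documented here). Removal counts are reported per criterion,
non-exclusively. Ro/e compares observed (cell type × group) counts with
the chi-square independence expectation e = row·col/total; o/e > 1
flags enrichment, and the e-weighted row mean of ratios is exactly 1.
Reference-gene signatures rank a candidate list (an explicit input —
the differential-expression pool that defines it upstream is not
reproduced here) by Spearman correlation with the reference gene across
cells, drop the reference itself, and keep the top 30 by default;
cell-level scoring of the resulting set reuses the gene-set score.
Downsampling draws up to 1000 cells per group uniformly without
replacement, keeps smaller groups whole, and is byte-identical per
seed.

## Synthetic-data generators

Each generator takes an explicit seed and uses one local PRNG stream;
identical seeds give byte-identical outputs, and every dataset carries
a `TruthBundle` (serializable to TOML) recording the planted
parameters.

- `gen_reference`: i.i.d. bases at a stated GC fraction (default 0.42,
  a mammalian-like value). No repeats, isochores or chromatin — only
  composition.
- `synthetic_signature_catalog`: a deterministic fixture of up to 30
  column-stochastic profiles. The two APOBEC analogs put 80% of mass on
  T[C>T]W resp. T[C>G]W; the rest are sparse Dirichlet draws. These
  imitate the shape of reference catalogs, not any published
  signature's values.
- `gen_catalog_cohort`: per-sample Poisson totals (default mean 500,
  a WES-scale load) and multinomial channel counts from a signature
  mixture whose APOBEC weight is Beta-distributed with mean
  `apobec_share` (default 0.2229) and concentration 20 — so the planted
  cohort share is the stated mean with realistic patient-to-patient
  spread.
- `gen_cohort_mutations`: places channel draws onto genome positions
  whose normalized trinucleotide matches, uniformly within context
  class; for the four APOBEC channels the base 5' of the TCW is a
  pyrimidine with probability `ytca_pyrimidine_prob` (default 0.7, the
  A3A-dominant regime that yields a ~7:3 YTCA:RTCA ratio). Positions
  are resampled rather than samples rejected, keeping per-sample counts
  exact (retry bound 10,000).
- `gen_survival`: exponential event times with hazard multiplied by
  `hr` above the score cutoff, independent exponential censoring tuned
  to the requested censored fraction, covariates independent of
  survival.
- `gen_bulk_expression`: Gaussian copula against the normal scores of
  the sample score, using the bivariate-normal conversion
  ρ_P = 2 sin(πρ_S/6) to hit target Spearman correlations, then
  exponentiated onto a TPM-like scale. Only rank structure is
  controlled; real cohorts' marginal distributions are not imitated.
- `gen_sc_cohort`: multinomial cell types per group; negative-binomial
  counts with planted co-expression modules (a shared per-cell latent
  factor, including a designated reference gene); QC metadata drawn
  in-bounds with a stated fraction of per-rule violations injected and
  recorded in the truth bundle.

Because the generators realize exactly the structure the estimators
assume (i.i.d. genomes, exponential hazards, copula ranks), passing
recovery tests demonstrates correctness of the implementations, not
robustness to the messiness of real cohorts (mutation clustering,
subclonality, batch effects, doublets).

## Problem sizes and determinism

The validation suite runs cohorts of 40–200 samples, genomes of
20–120 kb, 500-replicate-free null checks at 50–200 replicates, and a
permutation calibration at 50 replicates × 60 permutations — sizes at
which every planted effect is comfortably detectable while the whole
suite stays interactive. All stochastic tests fix seeds; hypothesis
property tests run derandomized.

## Known limitations

- Signature refitting assumes the reference catalog spans the true
  processes; unmodeled processes leak into the nearest profiles.
- The stage-1 enrichment null is gene-count-proportional and ignores
  gene length and regional mutability; it is not a driver test.
- The AMS context window treats N-free i.i.d. flanks as background;
  highly repetitive or N-rich regions simply drop out.
- Cox fitting inherits lifelines' behavior under near-separation;
  the wrapper surfaces convergence failures as errors rather than
  attempting penalization.
- The Ro/e enrichment flag is a point criterion (ratio > 1) with no
  uncertainty attached; replicate-level stability is left to the
  caller (the tests use seeded replicates).
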