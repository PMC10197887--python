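"""Build a 96-channel substitution catalog and mutation burden from a
simulated cohort.

Generates a 50 kb reference and 5 tumor samples whose mutations are
drawn from an 8-signature mixture, then tabulates pyrimidine-normalized
trinucleotide channels and tumor mutation burden (TMB, nonsynonymous
SNVs + indels per megabase of target territory).
"""

from apobecscan import (
    build_catalog,
    burden_table,
    compute_tmb,
    gen_cohort_mutations,
    gen_reference,
    synthetic_signature_catalog,
)

genome = gen_reference(50_000, seed=1)
signatures = synthetic_signature_catalog(8)
records, truth = gen_cohort_mutations(genome, 5, signatures, mean_mutations=300, seed=2)

catalog = build_catalog(records, genome)
print("catalog shape (samples x channels):", catalog.counts.shape)
top = catalog.counts.sum().nlargest(5)
print("five most-hit channels across the cohort:")
print(top.to_string())

burdens = compute_tmb(records, target_mb=38.0)
print("\nper-sample burden (mutations per Mb of a 38 Mb exome target):")
print(burden_table(burdens)[["n_nonsyn_snv", "n_indel", "tmb"]].round(2).to_string())
# A high share of T[C>N]W channels above reflects the two APOBEC-analog
# signatures in the simulated mixture.
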