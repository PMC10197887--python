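"""Dichotomize a per-sample score at the survival-optimal cutoff and
estimate the adjusted hazard ratio.

The generator plants a protective effect (hazard ratio 0.3) for samples
above score 1.5. The cutoff scan minimizes the log-rank p over
candidate thresholds; because the minimum over many tests is
anti-conservative, a permutation-adjusted p is also reported. A Cox
model with clinical covariates then estimates the group hazard ratio.
"""

import pandas as pd

from apobecscan import cox_ph, gen_survival, optimal_cutoff

cohort, truth = gen_survival(200, cutoff=1.5, hr=0.3, censor_rate=0.2, seed=5)

result = optimal_cutoff(cohort["score"], cohort, minprop=0.1, n_permutations=200, seed=5)
print(f"planted cutoff: {truth.params['cutoff']}, recovered: {result.cutoff:.3f}")
print(f"log-rank p at cutoff: {result.p_logrank:.2e} "
      f"(permutation-adjusted: {result.p_adjusted:.3f})")

for r in cox_ph(cohort, labels=result.labels, covariates=["age", "gender", "stage"],
                group_reference="low"):
    print(f"  {r.term:12s} HR {r.hr:5.2f}  (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})  p={r.p:.3g}")
# The 'group' hazard ratio should recover the planted 0.3 (high-score
# samples die at ~30% the baseline rate); covariates were simulated
# independent of survival, so their HRs hover near 1.
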