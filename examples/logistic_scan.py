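"""One-step logistic scan for a binary trait, with ML refit of top hits.

Builds a case/control cohort in which one SNP carries a true odds ratio
of 1.5 per dose unit, fits the covariate-only null model once, and runs
the one-step semi-parallel scan.  SNPs reaching log10 p <= -3 are then
refitted by fully iterated maximum likelihood: in this small-effect
regime the one-step and ML odds ratios should be nearly identical.
"""

import numpy as np

from semigwas import fit_null_logistic, simulate_binary_trait, simulate_genotypes
from semigwas.logistic import assoc_logistic, refit_top_snps, weighted_project_block

n, m = 2000, 200
rng = np.random.default_rng(7)
block = simulate_genotypes(n, m, seed=7)
X = np.column_stack([np.ones(n), rng.standard_normal(n)])  # one covariate
y = simulate_binary_trait(block.doses[:, 0], beta0=-0.3, beta1=np.log(1.5), seed=8)

ctx = fit_null_logistic(y, X)
print(f"null fit: {ctx.iterations} IRLS iterations, prevalence {y.mean():.3f}")

res = assoc_logistic(ctx, weighted_project_block(ctx, block), block.snp_ids)
refit, n_refit = refit_top_snps(res, y, X, block.doses, log10p_threshold=-3.0)

top = res.nsmallest(3, "log10_p").index
print(f"\nrefitted {n_refit} SNPs with log10 p <= -3; top hits:")
for j in top:
    print(
        f"  {res.snp_id[j]}: one-step OR {res.odds_ratio[j]:.4f} "
        f"(log10 p {res.log10_p[j]:.2f})  ->  ML OR {refit.odds_ratio[j]:.4f}"
    )
print(
    "\nsnp0 carries the true OR of 1.5; the one-step estimate sits slightly "
    "below the ML refit, as expected for the null-weight approximation."
)
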