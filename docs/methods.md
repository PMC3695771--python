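# Methods

## The semi-parallel linear scan

A GWAS fits, for each SNP dose vector *s* ∈ [0,2]ⁿ, the linear model
y = βs + Xγ + ε with a shared covariate matrix X (n × (k+1), intercept
included). The package never fits these m models individually. By the
Frisch–Waugh–Lovell theorem the SNP coefficient of the multiple
regression equals the slope of the residual-on-residual simple
regression, so the scan is:

1. factor X once (thin QR, orthonormal basis Q); residualize the
   phenotype: y* = y − Q(Qᵀy);
2. per block of SNP columns S (n × b): S* = S − Q(QᵀS), evaluated
   right-to-left so the largest intermediate is (k+1) × b, never n × n;
3. β̂ = (y*ᵀS*) ⊘ diag(S*ᵀS*) computed as two matrix-vector products;
   RSS_j = Σy*² − β̂_j² Σs*_j²; σ̂²_j = RSS_j/(n−k−2);
   se_j = √(σ̂²_j / Σs*_j²).

The residual degrees of freedom n−k−2 charge the intercept, the k
covariates and the SNP, even though the covariates were removed by
projection. Covariate coefficients γ are absorbed by the projection and
are not recoverable from the scan — by design; the SNP row is the
deliverable of a GWAS.

The scan pipeline uses a fused variant (`linear.scan_block`) that never
materializes S*: since y* ⊥ span(X), y*ᵀs* = y*ᵀs, and
Σs*² = Σs² − ‖Qᵀs‖². This halves the flops and avoids the n × b
intermediate; it is tested equivalent to the project-then-associate
route to ~1e-10 relative. Without covariates the same idea gives the
uncentered identities β̂ = Σỹᵢsᵢ / (Σsᵢ² − n s̄²) with ỹ = y − ȳ, so no
centered copy of the dose matrix is formed either.

Exactness is the contract: block results must match per-SNP textbook
least squares to 1e-8 relative, and they are invariant to replacing X
by X·T for any invertible T and to how the genome is partitioned into
blocks. The intercept requirement is checked as "the constant vector
lies in span(X)" (not "a literal ones column exists"), so
reparameterized covariate matrices pass through unchanged.

## The one-step logistic scan

Logistic regression is fitted by iteratively reweighted least squares
(Fisher scoring): at each iteration, weighted least squares of the
working response z = η + (y−p)/w on the design, with weights
w = p(1−p). The converged weights differ per SNP, which is exactly what
blocks vectorization. The package's approximation: fit the
covariate-only null model once (IRLS to convergence; defaults tol 1e-8
on the max coefficient change, 25 iterations, zero start — common GLM
practice, as no canonical values exist), then give each SNP a single
weighted least-squares step at the null weights w̃:

  β̂₁ = Σw̃ z* s* / Σw̃ s*²,  var(β̂₁) = 1/Σw̃ s*²,

with z*, s* the w̃-weighted residuals of z̃ and s against X. The null
working residual z* is SNP-free and computed once per scan. Two facts
matter:

- **The step is exact algebra.** β̂₁ and its variance equal the SNP
  coordinates of one full Fisher-scoring update of the (X, s) model
  started at (γ̂_null, 0) — the weighted Frisch–Waugh–Lovell identity.
  Tests verify this to 1e-10 against an independent single-step solve
  of the full normal equations.
- **The approximation error is in stopping after one step.** The
  shortfall grows with the true effect: the built-in bias study
  (1000 replicates, n=2000, true OR uniform on [1,5], intercept 0,
  doses uniform on [0,2]) shows the one-step odds ratio underestimating
  the ML odds ratio by ≈0.1% at an estimated OR of 1.33 (the median
  GWAS effect), ≈6% at OR 3, ≈17% at OR 5, read from a lowess smooth
  (span 0.5) of the per-replicate relative differences. The curve is
  ≈0 near OR 1 and rises monotonically; it is insensitive to the
  sample size. One-step p-values drift anti-conservative only in the
  extreme tail (−log10 p ≳ 25); the `refit_top` option re-fits full ML
  for SNPs beyond a chosen log10 p, recovering exact inference where it
  matters.

The simulation design choices the study needed but no convention
fixes: intercept β₀ = 0 (prevalence ≈ ½, the symmetric default,
exposed as a parameter), true OR drawn on the OR scale (not log), and
the lowess smoother above. The diagonal weight matrix is everywhere a
vector; "W times" is elementwise scaling, since materializing an n × n
diagonal is the memory trap the whole design avoids.

Wald statistics are referred to the standard normal in both models
(GWAS sample sizes make the t/normal distinction negligible); a
Student-t reference with n−k−2 degrees of freedom is available by flag
for small samples. Logistic Wald tests use the normal reference with no
degrees-of-freedom correction.

## Log-scale p-values

`log10_pvalue_twosided` computes log10 p = log10 2 + logΦ(−|t|)/ln 10
via the log-CDF, never 2(1−Φ(|t|)): the latter is exactly 0 in double
precision once p < ~1e-308 (and loses all relative precision long
before), while the log-tail form is finite and strictly decreasing for
arbitrarily large |t| (log10 p ≈ −349 at t = 40, ≈ −8688 at t = 200).
Tests pin it against the independent Mills-ratio asymptotic expansion
logΦ(−t) = −t²/2 − log t − ½log 2π + log(1 − t⁻² + 3t⁻⁴ − …). The
linear-scale `p` column is derived as 10^log10p and may underflow to 0;
`log10_p` is the authoritative output.

## Missing data

Individuals with missing phenotype or covariates are dropped from the
whole analysis (complete cases); every genotype block is subset to the
same rows. Missing genotypes cannot enter the block algebra (per-SNP
0/1 weights would break the shared projection), so: SNPs with call
rate below the threshold (default 0.95, boundary kept) are removed,
and remaining missing doses are imputed with the per-SNP mean of the
observed doses *in the analyzed sample* — imputation happens after the
complete-case subset so the mean matches the analysis population.
Imputation preserves observed entries and per-SNP means exactly.

At 95% call rate and n = 2000 this loses essentially nothing: with
genuine per-SNP effects (drawn N(0, 0.15²) in the validation study, so
the estimates have real between-SNP spread) the mean-imputed estimates
correlate > 0.99 with the complete-data estimates and no SNP with
|t| > 4 flips sign. The spread matters for the *metric*, not the
method: under a pure null both estimate vectors are sampling noise on
95%-overlapping data and their correlation is capped at √0.95 ≈ 0.975
for any n, which measures noise overlap rather than lost precision.

## Storage

The container is a single HDF5 file: dataset `dosage`, uint8, shape
(n_snps, n_individuals) — SNP-major, so one SNP is one contiguous
row — chunked (chunk_snps × chunk_individuals), plus string datasets
for SNP and individual IDs and attributes for the encoding. Doses are
stored as round(dose·100) ∈ 0..200 with 255 the missing sentinel:
quantization error ≤ 0.005, one byte per genotype (~2 GB for 10⁶ SNPs
× 2000 individuals). In memory, missing genotypes are the code 3.0,
outside the dose range.

PLINK v1 BED decoding is table-driven: a 256 × 4 lookup maps each
packed byte to four doses (bit-pairs least-significant first; 00 → 2,
10 → 1, 11 → 0, 01 → missing, counting the A1 allele; an
`allele_count="a2"` flag flips the orientation, since BED files do not
themselves record which allele the user wants counted). Row-per-person
dosage text (MACH-style: whitespace-delimited, two leading ID columns
by default, both configurable) is transposed into the container in
bounded memory, reading individuals in blocks and writing transposed
column slabs, so the peak buffer is individual_block × n_snps bytes
(~64 MB default) regardless of file size.

## Synthetic data: what it does and does not emulate

The generators produce independent doses (uniform on [0,2], or
binomial allele counts at given MAF), independent standard-normal
phenotypes/covariates, Bernoulli traits from a logistic dose-response,
and independent entrywise missingness. They validate the computation:
exactness of the algebra, calibration of type-I error (null scans
reject at 5% within binomial error), power/recovery of injected
effects, and the one-step bias profile. They deliberately do not model
linkage disequilibrium, realistic allele-frequency spectra, population
structure, relatedness, informative missingness, or
imputation-uncertainty correlation — so passing tests demonstrate the
*estimator and its implementation*, not robustness to those phenomena.
Relatedness correction and mixed models are out of scope.

## Problem sizes and numerics

Test and validation runs use scaled-down scans (hundreds to a few
thousand individuals, hundreds to 2000 SNPs); the algebra is linear in
both dimensions, so these sizes exercise every code path of a
full-size run. Numerical policies: rank deficiency of X is detected by
pivoted QR and reported with the offending column indices; a SNP whose
residual sum of squares falls at or below 1e-12·n is flagged
`monomorphic` (reported, not estimated) rather than erroring the scan;
negative RSS beyond a 1e-10 relative rounding allowance flags the SNP
`failed`; IRLS declares (quasi-)separation when any fitted probability
comes within 1e-10 of 0 or 1. Throughput is logged in Msips (millions
of SNP-individual pairs per second) as information only — it is a
property of the hardware, not of the method.
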