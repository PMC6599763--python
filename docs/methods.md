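# Methods

This note documents the models implemented in `pcovr_gxe`, the choices
made where the design was genuinely open, and what the bundled
synthetic-cohort generator does and does not emulate.

## Principal covariates regression (PCovR)

Given a column-centered predictor matrix `X` (n subjects × J
standardized SNP dosages) and a centered outcome `y`, PCovR finds R
orthonormal component scores `T = XW` minimizing

```
L(T) = α ‖X − T Pₓᵀ‖² / ‖X‖²  +  (1 − α) ‖y − T p_y‖² / ‖y‖²
```

with loadings `Pₓ = XᵀT` and `p_y = Tᵀy` profiled out.  The weight
α ∈ [0, 1] trades off summarizing the SNPs (α → 1, plain PCA) against
predicting the outcome (α → 0; at R = 1 the component is the
least-squares fitted-value direction, so `r²_y` equals the OLS R²).
The optimum is closed-form: `T` spans the top-R eigenvectors of
`G = α XXᵀ/‖X‖² + (1 − α) ŷŷᵀ/‖y‖²`, where `ŷ` projects `y` onto the
column space of `X`.  We compute this through one thin SVD of `X` and an
eigendecomposition of the r × r projected operator (r = rank(X)); this
single code path is algebraically identical to working with the n × n
form when J > n and the J × J dual otherwise, and is numerically
stabler.  Rank and pseudo-inverse tolerances are 1e-10 relative to the
largest singular value; eigenvector signs follow a fixed convention
(largest-magnitude entry positive) so ties resolve deterministically.
The test suite verifies the closed form against a 50-restart numerical
minimizer over orthonormal bases on random small instances.

### α selection

Model selection sweeps α over a coarse grid (0–1 in steps of 0.10) and a
fine grid (0.70–1.00 in steps of 0.01) at fixed R and records the
explained-variance curves `r²_X(α)` and `r²_y(α)`.  Picking the "knee"
of these curves by eye is common practice; we formalize it as an
explicit balance rule so runs are reproducible: among grid points
retaining at least `(1 − τ)`·`r²_X` of the value at the grid maximum
(default τ = 0.10), pick the α maximizing `r²_y`, breaking ties toward
larger α.  A manual override is accepted and logged.  The constraint set
always contains the maximal grid point for valid curves; degenerate
(non-finite) curves trigger a logged fallback to the maximal-`r²_y`
point.

### Number of components

`choose_n_components` supports a fixed R (default 5), a scree rule
(maximum second difference of the eigenvalues of `G`), and 10-fold
cross-validation of out-of-fold squared prediction error.  Plain
CV-error minimization reliably collapses to R = 1 under a null outcome
only once n is a few hundred per fold-model; the tests exercise it at
n = 400.

## Quartimin rotation

Components are obliquely rotated to simple structure by minimizing the
quartimin criterion `Q(Λ) = Σⱼ Σ_{r≠s} λ²ⱼᵣ λ²ⱼₛ` with a
gradient-projection iteration over transformations with unit-length
columns: step along the projected negative gradient, renormalize, halve
the step until the criterion decreases.  The criterion is non-increasing
across accepted iterates by construction; convergence is declared when
the change drops below 1e-8 (at most 1000 iterations), with up to 10
seeded random orthonormal restarts if the running transformation becomes
singular.  Rotated scores are rescaled to unit SD — with the loadings
absorbing the inverse scale — so the model-implied reconstruction
`T Pₓᵀ` is preserved exactly (machine precision) while downstream models
receive standardized component scores; the component correlation matrix
Φ then has unit diagonal.

## Genotype QC

Filters run in a fixed, logged order: subject call rate → SNP call rate
→ minor-allele frequency → Hardy-Weinberg exact test.  Defaults are 0.95
call rate on both margins, MAF ≥ 0.01 and HWE α = 1e-6; all four are
exposed in configuration, and every removal is logged with a reason
code.  The HWE test is the plain (not mid-p) exact conditional test:
condition on the allele counts, sum the probabilities of all
heterozygote counts at most as probable as the observed one; the tests
compare it against a full-enumeration oracle in exact rational
arithmetic.  Minor alleles are defined panel-wide on the analysis
sample, not per subpopulation.  Missing dosages are imputed by the
per-SNP observed mean (2·MAF) before per-column standardization —
adequate when missingness is sparse, which the QC call-rate filters
enforce; LD-aware imputation is out of scope.

## Measurement model and sG×E growth model

The parenting environment is a single latent factor measured by 9
indicators (3 informants × 3 waves), fit by maximum likelihood with the
factor variance fixed to 1.  Complete data use the EM/SVD factor-
analysis path; missing indicators use our full-information likelihood
over missingness patterns.  Heywood cases are bounded at 1e-6 with a
warning.  Factor scores are Bartlett (weighted least-squares) estimates
from each subject's observed indicators, then standardized.

The outcome follows a linear latent growth curve over three waves with
fixed time codes (0, 1, 2), making the intercept the wave-1 level; the
codes are configurable.  Both growth factors are regressed on the
standardized parenting score, all standardized component scores, the
focal component × parenting product (components and parenting are
standardized *before* the product is formed), and the covariates sex,
age and family structure.  Estimation is ML: with complete outcomes, an
iterated-GLS closed form (the three-wave covariance is just-identified
by the intercept/slope variance-covariance plus per-wave residuals, so
the structured solve is exact); with missing outcomes, quasi-Newton
full-information likelihood over missingness patterns, started from the
complete-case solution.  Exogenous predictors with missing values are
handled complete-case; outcomes and indicators by full information.

Standard errors are Huber-White sandwich estimates over subject-level
likelihood contributions (observed information bread, outer-product
meat, both by numerical differentiation), emulating robust "MLR"-style
inference; model-based SEs are also recorded and agree with the robust
ones within 10% at n = 2000 under correctly specified normal errors.
Standardized coefficients rescale `b` by the sample SD of the predictor
over the model-implied SD of the growth factor; the tests recompute this
contract directly.  Gene-environment correlations are reported as sample
correlations among the standardized exogenous scores, which is the ML
estimate under the two-step approach.

**Two-step interaction and attenuation.**  The latent-by-observed
interaction uses products of standardized Bartlett scores rather than
latent moderated estimation.  With the default 9-indicator, loading-0.7
measurement design the Bartlett score reliability is about 0.90, which
attenuates the interaction coefficient by roughly 5 percent (recovery
simulations at a true coefficient of 0.10 center near 0.095); coverage
of the robust 95% CI stays near nominal at n = 1000.  Full LMS-style
numerical-integration estimation is a declared non-goal.

**Quadratic robustness.**  Unmodelled quadratic effects of correlated
predictors leak into the product term and create spurious interactions.
With a true quadratic effect (0.15), gene-environment correlation 0.3
and no true interaction, the model without squared terms rejects the
null interaction in roughly 90% of replicates; adding the squared focal
component and squared parenting as predictors returns the rate to the
nominal 5%.  `quadratic_robustness` automates this refit and reports
whether the interaction's significance classification changes.

## Synthetic cohorts

`SimulationConfig` defaults define the study-scale conditions: 1000
subjects; 223 SNPs in 14 gene blocks of realistic, unequal sizes;
within-block LD 0.7; MAF drawn uniformly on (0.05, 0.5); three annual
outcome waves on a mean ≈ 2.5 scale (growth SDs 0.6/0.2, residual SD
0.4); 9 parenting indicators with loadings 0.7 and unit variance;
genotype missingness 1% (sparse, "few missing" regime), outcome
missingness 0 by default (the FIML path is exercised separately at 20%
MCAR).  Genotypes are generated by thresholding two correlated latent
Gaussian haplotype draws per block at the per-SNP allele-frequency
quantile, which yields Hardy-Weinberg-consistent 0/1/2 codes with
controllable block correlation; population structure uses
Balding-Nichols Beta-distributed subpopulation frequencies with
parameter Fst.  The causal polygenic score spreads small weights over
all SNPs (N(0, 1/J) per SNP, fixed by the seed) unless explicit weights
are supplied.  Gene-environment correlation is zero unless the `rge`
knob is set.  Covariates (sex, age, family structure) are generated with
zero causal effect.

What the generator does **not** emulate: item-level Likert responses
(outcomes are unbounded continuous values, matching how such scores are
analysed), realistic recombination maps or haplotype sharing beyond the
exchangeable block correlation, informant-specific method variance,
ascertainment, and non-MCAR missingness.  Passing recovery tests
therefore demonstrate correctness of the estimators under the assumed
generating model, not robustness to violations of it.

## Problem sizes used in the checks

The automated checks use sizes chosen to keep the full suite fast while
leaving Monte Carlo error well inside the asserted bands: 100 random
instances for the closed-form/brute-force comparison (50 restarts each);
50 seeded fixtures for quartimin recovery; all genotype triples to total
60 for the HWE oracle; 200 replicates at n = 1000 for interaction
recovery and coverage; 500 replicates for the type-I and
spurious-interaction rates; and a single-seed deterministic rerun of the
full study-scale pipeline (n = 1000, J = 223).

## Known limitations

- The two-step interaction estimate is mildly attenuated (documented
  above); product-indicator or LMS estimation would remove this at
  substantial complexity cost.
- The LD-mirror diagnostic's similarity/r² correlation is diluted when
  several high-LD blocks exist but only one is loaded; the block-
  concentration condition carries most of the decision in that regime.
- Mean imputation ignores LD; with the default call-rate filters the
  imputed fraction is small.
- Wave residual variances are homoscedastic and independent by default;
  within-informant correlated indicator residuals are not modelled.
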