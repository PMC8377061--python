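# Methods

## Model

For `p` traits measured on `n` genotyped individuals, let `G` be the `n×n`
genetic relationship matrix estimated from allele-frequency-standardized
SNP dosages, `G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))`.
Phenotypes are residualized on nuisance covariates and rank-transformed to
normal quantiles, so the model assumes zero mean:

```
vec(Y) ~ N(0,  Σ_g ⊗ G + Σ_e ⊗ I_n)
```

The genetic covariance `Σ_g = Λ_a Λ_aᵀ` and residual covariance
`Σ_e = Λ_e Λ_eᵀ` are parameterized through loading matrices, each block
either a Cholesky factor (saturated; `p(p+1)/2` free loadings) or an
independent-pathway structure (one common column plus a specific diagonal;
`2p` loadings, identified for `p ≥ 3`).  All latent factors have unit
variance.  This is an AE decomposition: no shared-environment component is
modeled, because unrelated-sample GRM designs cannot separate it from E.

### Identification conventions

Sign flips of whole loading columns leave `Λ Λᵀ` unchanged, so estimates are
canonicalized after optimization: Cholesky diagonals non-negative, the
common factor's first nonzero loading non-negative, specific loadings
non-negative.  The free-parameter vector is ordered genetic block first,
then residual block, column-major within a block, which makes saved fits
portable.

## Likelihood engines

**Rotation** (complete cases).  With `G = U D Uᵀ` computed once per fit,
the rotated data `Y* = Uᵀ Y` have independent rows with covariance
`d_i Σ_g + Σ_e`.  Each likelihood evaluation solves the generalized
eigenproblem `Σ_g φ = μ Σ_e φ`; in that basis every per-individual log-det
and quadratic form is diagonal, so one evaluation costs `O(p³ + n p)`.
A singular `Σ_e` at the evaluation point returns `−inf` (not an exception),
which the optimizer treats as a large penalty.

**Direct** (full-information, accepts missingness).  The covariance
`Σ_g ⊗ G + Σ_e ⊗ I` is assembled explicitly over the observed
trait-individual entries and evaluated as one multivariate-normal
log-density.  Memory and cubic cost bound this to roughly `n·p ≤` a few
thousand; it exists to handle union samples (every individual with at least
one observed trait) and as the brute-force cross-check of the rotation
engine — the two agree to ≤1e-6 on complete data, which is a tested
invariant.

The published analyses this design follows report per-model Ns larger than
any single trait's N, implying a union-sample likelihood; at desk scale we
default to the rotation engine on complete cases and expose the direct
engine for union-sample runs on reduced n.  (Full-scale multivariate fits
of this kind are reported to take weeks of CPU; that scale is explicitly
out of reach here.)

### Numerical choices

* GRM eigenvalues are floored at **zero** (negatives clipped; an eigenvalue
  below −1e-4 raises a conditioning error).  A small positive floor was
  considered and rejected: the GRM always carries one exact-zero eigenvalue
  (in-sample standardization centers the SNP matrix), and inflating it
  desynchronizes the rotation and direct engines by more than their 1e-6
  agreement contract, while a zero eigenvalue is harmless — the residual
  covariance keeps every rotated observation nonsingular.
* Optimization: L-BFGS-B with numerical gradients from `n_starts` (default
  5) initializations.  Start 0 maps half the complete-case sample
  covariance into each block (Cholesky factor, or leading eigenvector plus
  diagonal remainder for IP blocks); later starts multiply it by lognormal
  noise with sd 0.3, seed-controlled.
* Observed information: central finite differences of the log-likelihood
  (relative step 1e-4, absolute floor 1e-6, symmetrized), with one
  stencil-shrink retry on non-finite evaluations.  If the information is
  not positive definite — typical when an estimate sits on a boundary or
  the design carries no relatedness contrast — SEs are reported missing
  with an explanatory message rather than silently pseudo-inverted.
* Model comparison: `AIC = −2LL + 2k`, `BIC = −2LL + k·ln(n)` with `n` the
  number of individuals in the analysis sample.  LRTs against the saturated
  Cholesky model use naive df counting (`Δdf = k_sat − k`) with the plain
  chi-square reference, no boundary mixture correction — matching how such
  tables are conventionally printed.  A model beating the saturated
  likelihood by more than 1e-4 raises a dataset-mismatch error; smaller
  negative deviances are clamped to zero as optimizer slop.
* Delta-method SEs for derived statistics (correlations, heritabilities,
  factorial co-heritabilities, genetic covariances) use central-difference
  Jacobians of the parameter-to-statistic map sandwiched with the inverse
  observed information.  The bivariate-heritability SE is approximated by
  `SE(σ_g12)/σ_p12`, treating the sampling error of the phenotypic
  covariance as negligible.
* 95% intervals are Wald: estimate ± 1.96·SE.
* Wald tests per loading are flagged at 0.05 and at a stricter 0.007
  experiment-wide threshold; the latter is consumed as a configuration
  constant, not derived (effective-number-of-tests machinery is out of
  scope).

## Phenotype preparation

Residualization is per-trait OLS (intercept always included) on that
trait's observed rows; traits mapped to an empty covariate list pass
through untouched (for scores that arrive pre-standardized).  The rank
transform uses the Blom offset, `Φ⁻¹((r − 3/8)/(n + 1/4))`, with average
ranks for ties — the prevailing convention in statistical genetics; results
should not be sensitive to the offset choice, and the transform is
idempotent on already-normal scores to <1e-6.  Relatedness pruning removes,
greedily and deterministically (max over-threshold degree, ties by ID sort
order), individuals until no GRM off-diagonal exceeds the cutoff (default
0.05).  The original pruning order behind such published analysis sets is
typically unstated; the greedy rule retains the most individuals in common
cases and is reproducible, which is what matters for this package.

## Synthetic data

The generator emulates a population cohort of unrelated youths with five
or six standardized psychometric traits: per-SNP allele frequencies uniform
on a MAF range, Hardy-Weinberg binomial dosages without LD, GRM estimated
in-sample, and phenotypes drawn from the factor model (genetic factor
scores `~ N(0, G)` via the symmetric square root of `G`, residual scores
iid).  Missingness is injected per trait, completely at random.  All
randomness flows from one scenario seed through a spawned `SeedSequence`
tree, so each sub-draw is independently reproducible.

Preset `multidomain` states a five-trait world — spelling, phonemic
awareness, passage reading, listening comprehension, non-word repetition —
with common-factor phenotypic-variance shares (0.27, 0.31, 0.45, 0.13,
0.14), specific genetic factors only for the last two (0.17, 0.12), hence
truth heritabilities (0.27, 0.31, 0.45, 0.30, 0.26), inside the 0.30–0.50
range reported for such traits where the structure allows.  Residual
correlations use the reported values where available (0.67
spelling–reading; 0.02, 0.11, 0.08 for the language cross-domain pairs);
the remaining cells are illustrative moderate/weak values because the full
residual covariance is not published.  Missingness rates (0.13, 0.11,
0.22, 0.17, 0.18) are derived from the per-trait and per-model sample
sizes of the source cohort.  Preset `reading_fluency` states six
reading-fluency measures with common shares 0.27–0.47 and small specific
factors; `null_pleiotropy` has diagonal genetic loadings for
type-I-error-style checks.  Default scale is n = 1000, m = 5000 — the desk
scale at which recovery properties are tested; the source cohort's scale
(N ≈ 6500, ~466k SNPs) is simulable for phenotypes but not fittable in
reasonable desk time.

**What a green test establishes — and does not.**  Simulated SNPs are
independent with in-sample-estimated frequencies, individuals are exactly
unrelated, missingness is MCAR, and residual truth is partly illustrative.
Recovery results therefore validate the estimator under its own
assumptions; they say nothing about LD, stratification, assortative
mating, or informative missingness in real cohorts.  One consequence worth
knowing: because the illustrative residual block departs from a one-factor
structure only weakly, BIC at desk-scale n can prefer the fully
independent-pathway model over IPC — with ~700 complete cases the residual
misfit of IP is too small for BIC's penalty gap.  The published full-scale
analyses reject IP decisively; reproducing that contrast would need either
a stronger residual deviation than the printed values support or the full
sample size.  The tested selection property is the one the data can
support at this scale: IPC beats the saturated Cholesky model by BIC in at
least 8 of 10 replicates when the truth is IPC.

## Known limitations

* No REML — the likelihood is plain ML on pre-residualized zero-mean
  phenotypes, so fixed-effect uncertainty is not propagated.
* No LD-aware or external-frequency GRMs; allele frequencies are always
  in-sample.  No PLINK .bed parsing (dosage matrices or GCTA binaries in).
* Direct-engine union fits are cubic in the number of observed entries;
  practical to n of a couple thousand.
* Boundary estimates (zero loadings) get missing SEs rather than
  mixture-corrected inference.
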