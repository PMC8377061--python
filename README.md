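# gsemkit

Structural equation modeling of multivariate genetic and residual covariance
on genetic relationship matrices (GRMs).

## The problem

In samples of unrelated, genotyped individuals, the covariance between any
two trait measurements can be split into a part tracking realized genome-wide
relatedness (additive genetic, **A**) and a residual part (**E**).  Classic
GREML estimates one SNP heritability, or one genetic correlation, at a time.
This package instead fits **factor structures** to the full multi-trait
genetic and residual covariance — the twin-study modeling toolkit transferred
to GRM data — so you can ask *how* a set of traits shares its genetic
variance: one pleiotropic factor?  trait-specific influences?  both?

The data model for stacked traits `vec(Y)` is zero-mean multivariate normal
with covariance

```
Σ_g ⊗ G + Σ_e ⊗ I,     Σ_g = Λ_a Λ_aᵀ,  Σ_e = Λ_e Λ_eᵀ
```

where `G` is the GRM and `Λ_a`, `Λ_e` are loading matrices structured as

* **Cholesky** (saturated): trait *j* loads on factors *1..j*; `p(p+1)/2`
  parameters per block, spans any PSD covariance;
* **independent pathway (IP)**: one common factor plus one specific factor
  per trait; `2p` parameters per block; or
* **IPC** (hybrid): IP genetic block, Cholesky residual block — an
  interpretable genetic structure without constraining the residuals.

Models are fit by maximum likelihood (rotation engine on complete cases,
or a full-information direct engine under missingness), compared by LRT /
AIC / BIC, and summarized as genetic correlations
`r_g = σ_g12 / √(σ²_g1 σ²_g2)`, SNP heritabilities, factorial
co-heritabilities `f²_g(i,t) = σ²_g_it / σ²_g_t` (the share of a trait's
genetic variance owned by factor *i*), and bivariate heritabilities
`h²_biv = σ_g12 / σ_p12`, each with delta-method SEs.

Intended users: statistical geneticists analyzing multi-trait cohorts with
genome-wide genotypes, and methodologists who need a transparent, testable
reference implementation with a built-in simulator.

## Worked example

```python
import gsemkit as gk

# five traits, one shared genetic factor + specific factors for two traits
scenario = gk.preset("multidomain", n=1000, m=5000, seed=11, missing=False)
grm, pheno = gk.simulate_study(scenario, route="genotype")
dataset = gk.align(pheno, grm, mode="complete", require_transformed=False)

fits = {name: gk.fit_ml(gk.from_preset(name, scenario.trait_names),
                        dataset, n_starts=3, seed=0)
        for name in ("cholesky", "ipc")}
table = gk.compare_models(fits, fits["cholesky"], dataset.n)
print(table[["LL", "k", "AIC", "BIC", "p_value", "selected"]].round(2))
```

prints

```
               LL   k       AIC       BIC  p_value  selected
model
cholesky -6166.29  30  12392.58  12539.82      NaN     False
ipc      -6168.00  25  12386.00  12508.70     0.64      True
```

— the hybrid IPC model loses only 1.7 log-likelihood units to the saturated
model while spending 5 fewer parameters, so BIC selects it (the LRT p = 0.64
says the genetic one-factor restriction is consistent with the data).
Derived statistics from the selected fit:

```python
h2, h2_se = gk.snp_heritability(fits["ipc"])
rg, rg_se = gk.genetic_correlations(fits["ipc"])
```

```
SNP-h2 (SE):
  spelling         0.43 (0.09)
  phon_aware       0.50 (0.10)
  passage_reading  0.53 (0.09)
  listening_comp   0.28 (0.09)
  nonword_rep      0.23 (0.10)

r_g passage_reading vs listening_comp: 0.59 (SE 0.15)
```

The simulation truth puts every heritability between 0.26 and 0.45 with a
strong common factor; at n = 1000 the estimates recover the truth within
about one SE.  A command-line layer wraps the same workflow:

```bash
gsemkit simulate --preset multidomain --n 1000 --m 5000 --seed 7 --out-prefix sim/study
gsemkit pipeline run --config study.yaml
```

## Acceptance script

`scripts/acceptance.py` exercises the package end to end: it simulates a
five-trait study at the generator's default scale (genotype-level route),
runs the complete modeling stage — relatedness pruning at 0.05, covariate
residualization, rank-based inverse-normal transform, GRM alignment,
Cholesky/IP/IPC fits, BIC selection, derived statistics, proxy selection —
and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Intermediate artifacts (GRM triplet, phenotype TSV, stage reports) land in
`results/acceptance_run/`.

## Documentation

`docs/methods.md` describes the likelihood engines, identification
conventions, standard-error machinery, the synthetic-data generator and its
limitations, and the numerical choices made throughout.
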