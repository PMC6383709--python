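# phenoselect

Quantitative-genetic analysis of breeding phenology in pedigreed wild bird
populations: is lay date under stabilizing selection, where is the fitness
optimum, and is there enough additive genetic variance (or plasticity) for
the population to track it?

The package was built around the situation of a small, closed, intensively
monitored island passerine population — every clutch recorded, a
multi-generation pedigree with widespread extra-pair paternity, daily
temperatures from a nearby station — but all components work on any
records/pedigree/temperature triple in the documented CSV layout, and a
synthetic-data generator produces a complete fake study with known ground
truth so the entire pipeline runs (and is tested) with no data downloads.

## What it computes

**Fitness-optimum model.** For breeding record *i* in season *j(i)* with
standardized lay date *x·ᵢ*, the latent expected fitness is a Gaussian
curve

> Zᵢ = A · exp(−((xᵢ − λ_{j(i)}) / σ)²),  λⱼ = μ + B·θⱼ + uⱼ,
> uⱼ ~ N₍₋₂,₂₎(0, σᵤ²)

observed through Yᵢ ~ Poisson(Zᵢ) (recruit or egg counts) or
Binomial(nᵢ, Zᵢ) (stage survival, with A ≤ 1). Priors: μ ~ U(−2,2),
σ ~ U(0,100), A ~ U(0, A_max), 1/σᵤ² ~ Γ(0.001, 0.001), cue slope
B ~ N(0, 10⁶). Fitted by adaptive Metropolis-within-Gibbs in multiple
chains with split-chain Gelman–Rubin PSRF diagnostics, posterior
predictive checks (zero-count enrichment), and pMCMC sign tests for B.
The optimum μ is reported on the day scale against the lay-date mode
(kernel-density argmax).

**Animal model.** A Bayesian Gaussian mixed model for lay date with
additive genetic (pedigree **A**-matrix), permanent-environment, social
mate and year random effects and clutch number fixed:

> h² = V_A / (V_F + V_Mate + V_PE + V_A + V_R),
> r² = (V_A + V_PE) / (same denominator)

i.e. heritability over the within-year phenotypic variance, with V_F the
variance of the fixed-effect predictor. Random-effect variances carry
parameter-expanded priors (sd ~ half-Cauchy(√1000), equivalently
variance/1000 ~ F(1,1)); the residual prior is IG(0.01, 0.01). A
mother–daughter regression estimator (h² = 2 × slope) is included, as is
a pedigree-simulation power study (gene-dropped breeding values plus
equal-variance PE/mate/year effects at a target h²).

**Selection statistics.** Robertson's selection differential
S = cov(lay date, relative fitness) with non-parametric bootstrap SEs, and
Lande–Arnold standardized gradients β, γ from the quadratic regression of
relative fitness on standardized lay date.

**Phenology GLMMs.** Start of breeding season, reclutching and female
survival via Gaussian/binomial/Poisson mixed models with crossed random
intercepts (exact ML/REML for Gaussian, Laplace for the rest), candidate
broken-line age models (breaks at ages 2 and 6, first-year offset,
per-transition slopes), the 50-day pre-season temperature cue, and the
stepwise AIC procedure (screen each variable against the null, full model
of survivors, drop-one to a fixed point, most parsimonious model within
ΔAIC < 2).

## Worked example

```python
from phenoselect import generate_breeding_data
from phenoselect.records import prepare_dataset
from phenoselect.optimum import GaussianOptimumModel, trait_mode
from phenoselect.selection import SelectionStats

study = generate_breeding_data(seed=1)          # synthetic study, known truth
prep = prepare_dataset(study.records, study.temperatures)
recs = prep["records"]

model = GaussianOptimumModel(family="poisson", a_max=5.0,
                             n_chains=2, n_iter=12_000, burn_in=2_500, seed=1)
model.fit(recs, response="n_recruits", standardizer=prep["lay_standardizer"])
opt = model.optimum_summary()
mode = trait_mode(recs["lay_day"].to_numpy())
sel = SelectionStats.compute(recs["lay_day"], recs["n_recruits"], n_boot=2000, seed=1)

print(f"fitness optimum: {opt['calendar']['median']} "
      f"[{opt['calendar']['lower']} - {opt['calendar']['upper']}]")
print(f"lay-date mode:   {mode['calendar']} (day {mode['mode_day']:.1f})")
print(f"selection differential: {sel.S:.2f} days (SE {sel.S_se:.2f})")
print(f"gradients: beta = {sel.beta:.3f} ({sel.beta_se:.3f}), "
      f"gamma = {sel.gamma:.3f} ({sel.gamma_se:.3f})")
```

prints

```
fitness optimum: October 2 [September 27 - November 27]
lay-date mode:   November 8 (day 68.0)
selection differential: -7.13 days (SE 1.00)
gradients: beta = -0.245 (0.046), gamma = -0.159 (0.068)
```

The posterior median of the optimum sits in early October while the bulk
of the population lays in November: directional selection for earlier
laying (negative S and β) together with stabilizing curvature (negative
γ). Day counts are days since 1 September of the season's starting year.

The same analyses run from the shell:

```bash
phenoselect all --fixture tiny --seed 1 --out report/
phenoselect optimum --fixture default --seed 1 --out report/
phenoselect fixture --size tiny --out data/   # write the CSVs themselves
```

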