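# Methods

This note documents the models, the samplers, the synthetic-data
generator and the numerical choices behind `phenoselect`, in the spirit of
a statistical methods appendix: enough detail to re-derive every estimate
the package produces, and an explicit account of what the simulation-based
tests do and do not establish.

## Data model and derived variables

A *breeding record* is one clutch: female and social male identifiers,
season (labelled by its starting calendar year; the breeding season runs
September–February, so records dated September–December belong to that
year's season and January–August to the previous one), lay/hatch/fledge
dates in season days (days since 1 September; 1 Sept = 0), stage counts
(eggs ≥ hatchlings ≥ fledglings ≥ recruits), clutch number, female age,
tarsus length and inbreeding coefficient. Records missing a lay date but
with a hatch date are imputed as hatch − 17 days and flagged; records with
neither are excluded with a logged warning.

Clutches are numbered 1..k within female × season in lay-date order,
regardless of success; ties break by hatch date, then stable input order,
and are logged. *Start of breeding season* is the lay date of clutch 1.
*Fitness* of a clutch is the number of its offspring that later breed
("recruits"), recomputed from the pedigree: an offspring is credited to
its clutch only if its dam is known, and counts as a recruit if it appears
as a dam or (social or genetic) sire in any later season. Final-season
records are flagged — their offspring cannot yet be observed recruiting.

The *temperature cue* of season j is the mean daily maximum temperature
over the 50 days strictly before the grand-mean start of breeding (one
anchor date computed across all seasons, applied to each season's
calendar). Up to 10% of window days may be missing (mean over available
days); beyond that the season's cue is set missing with a warning. The
grand mean uses every season in the prepared data; restricting to a
subset of seasons with temperature coverage is a caller-side filter.

Standardization is mean-centring and scaling by the sample (n−1) SD; the
transform is retained so optima can be reported in days and calendar
dates.

## Pedigree algebra

The additive relationship matrix **A** uses the tabular method with
unknown parents treated as unique unrelated founders. Inbreeding is
F = diag(**A**) − 1, but *reported* as missing for any individual with an
unknown parent or grandparent, since missing ancestry biases F towards
zero — the convention for wild pedigrees with partial parentage. Depth is
the longest known-ancestor chain (founders = 0); because published mean
depths sometimes count founders as generation 1, both conventions are
returned.

Breeding values are simulated by gene dropping: founders ~ N(0, σ²_A);
an individual with both parents known receives the mid-parent value plus
a Mendelian deviation of variance σ²_A(½ − ¼(F_dam + F_sire)); a missing
parent's share is replaced by an independent founder draw with the
variance that keeps Var(BV) consistent with the tabular **A**. The test
suite verifies Cov(BV) ≈ σ²_A·**A** by Monte Carlo and checks **A**
against an independent gene-dropping (allele-sharing) oracle.

## Mixed models and AIC selection

One engine fits all phenology GLMMs: random-intercept models with any
number of crossed grouping factors, Gaussian (exact marginal likelihood,
ML and REML — verified to 4+ decimals against lme4 during development),
binomial-logit and Poisson-log (Laplace approximation, the standard
single-quadrature GLMM likelihood). Because only random intercepts occur,
every Z-product reduces to index aggregation; the inner Newton solves a
dense (p+q)×(p+q) system, and the outer Nelder–Mead runs on the
log-variances. AIC = 2k − 2lnL always uses the ML likelihood with
k = fixed coefficients + variance parameters; Gaussian point estimates
are reported at REML; Wald z/t statistics stand in for lmerTest-style
per-coefficient tests. Aliased (collinear) columns are tolerated via
least-squares/pseudo-inverse solves — the likelihood is unaffected and
AIC still counts the redundant parameter, which is what lets the
stepwise procedure discard duplicate predictors on parsimony grounds.

Candidate age models: linear; quadratic; broken-line with hinge terms
max(0, age − k) at k = 2 or k = {2, 6}; one bounded ramp per age
transition; and a first-year variant (indicator(age = 1) + linear +
hinge at 6) — a discontinuous broken line with breaks at ages 1 and 6.
Both break parameterizations are provided because the two are nearly
equivalent on data where first-year females lay ~12 days late and the
delay resumes after age 6.

The stepwise AIC procedure: (1) each candidate alone vs the null model,
discarding candidates that do not improve AIC by more than 2 (the
"significant on its own" screen is operationalized as ΔAIC > 2); (2) full
model of survivors; (3) repeated drop-one comparisons to a fixed point
(the best predictive model); (4) the best *inferential* model is the most
parsimonious model within ΔAIC < 2 of the best predictive one, chosen
over every model evaluated along the trace. Deterministic given data and
candidate order; the full trace is returned and serializable as TSV.
Inbreeding, which deletes many rows, is meant to be tested in a separate
reduced-data pass, never pooled with the main selection; the year trend
test (year as standardized continuous fixed effect, with and without the
year random intercept) is a pipeline switch.

## The animal model and its sampler

Lay date (days) = intercept + clutch-number effect + a + pe + mate + year
+ residual, with a ~ N(0, σ²_A **A**). Only phenotyped females need
genetic effects: the sampler marginalizes **A** to the phenotyped subset
(exact, since unphenotyped individuals carry no data). Blocked Gibbs
updates: fixed effects and each iid random-effect block are conjugate
draws (iid blocks have diagonal conditional precision because each record
carries one level per factor); the genetic block is drawn exactly in a
whitened eigenbasis — with D the per-female record counts and
M = D^(−1/2) A_obs^(−1) D^(−1/2) = UΛU′ computed once, the conditional
precision in the rotated basis is diagonal (1/σ²_R + Λ/σ²_A), so the
per-sweep cost is two q-vector rotations.

Priors. The four random-effect variances use the parameter-expanded
(V = 1, ν = 1, α_μ = 0, α_V = 1000) specification, whose marginal with a
central α is variance/1000 ~ F(1,1), i.e. sd ~ half-Cauchy(√1000); they
are updated by adaptive Metropolis on the log-variance against this
marginal density (equivalent to, and simpler than, literal
parameter-expansion Gibbs). The residual variance has the conjugate
IG(ν/2, νV/2) = IG(0.01, 0.01) update. Proposal scales adapt towards 44%
acceptance during burn-in only, so the post-burn-in chain is a fixed
Markov kernel.

Defaults follow the full study protocol (500,000 iterations, thin 10,
burn-in 3,000, targeting ESS > 8,000 per parameter; an ESS warning fires
below the threshold). Per posterior draw the sampler stores all variance
components, V_F = Var(Xβ) over the observed design (population 1/n
variance — the balanced-binary closed form d²/4 is exact under this
convention), V_P = V_F + V_Mate + V_PE + V_A + V_R (year excluded), and
the ratios h² and r². Summaries are posterior mode (kernel-density
argmax), median, and 95% HPD or equal-tail interval. Ratios are formed
per draw; the mode of the ratio draws is not the ratio of component
modes, and both conventions can be reported from the draws.

The mother–daughter regression uses per-female mean lay dates; under a
single-parent regression E[slope] = h²/2, so the default reports
h² = 2 × slope, flagged prominently since published values are sometimes
the raw slope.

Convergence: Heidelberger–Welch stationarity (Cramér–von Mises on the
Brownian bridge of cumulative sums, batch-means spectral density at zero,
progressive 10% discards to 50%) and half-width tests per parameter, plus
Geyer initial-monotone-sequence ESS. Multi-chain runs add the classic
split-chain Gelman–Rubin PSRF (identical chains give √((n−1)/n);
pass threshold 1.1).

## The fitness-optimum model and its sampler

Model and priors as in the README. The sampler is adaptive
Metropolis-within-Gibbs with Gaussian proposals *reflected* at the prior
bounds (reflection keeps the proposal symmetric, so no Hastings
correction); the year effects u_j touch disjoint data given the global
parameters and are proposed jointly with vectorized per-year
accept/reject; σ_U² uses a log-scale Metropolis step whose target
includes the truncated-normal normalizing constants of the u_j (computed
via erf on the symmetric interval — the cdf-difference form cancels
catastrophically for large σ_U and once allowed the near-scale-free
Γ(0.001, 0.001) precision prior to wander to astronomically large
variances). The log-likelihood is evaluated as y·(log A − d²) − exp(·),
never log(exp(·)), so records far from the optimum cannot underflow to
0·log 0. Truncation semantics follow the model definition: u_j and μ are
each bounded in [−2, 2]; λ_j = μ + u_j may then exceed the interval, the
per-draw frequency of which is reported, and a strict mode clips λ
directly. A per-female random effect exists behind a flag, default off.

Defaults follow the study protocol (8 chains × 50,000, thin 10, burn-in
3,000, total post-thin draws ≥ 10,000 asserted). Fitting the optimum is
gated on a quadratic pretest — a GLMM with linear + quadratic lay date vs
linear only, proceed iff ΔAIC > 2 — with an override flag. Posterior
predictive checks simulate replicate datasets from posterior draws and
compare the zero-count fraction; the lay-date mode comes from the binned
kernel density (below). Robustness subsets (middle-aged females, females
surviving to the next year, annual fitness) are record filters reusing
the same model.

Sampler validation: on a one-parameter toy (single year, σ and A fixed)
the sampled posterior matches a dense grid approximation within total
variation 0.05; at the study's scale (16 years, 1,400 records) 95%
credible intervals cover each generating parameter in ≥ 90% of seeded
replicates. Joint coverage of all four 95% intervals simultaneously is
mathematically capped near 0.95⁴ ≈ 0.81 for any calibrated posterior, so
calibration is asserted per parameter.

## Selection statistics

Relative fitness w = W/mean(W). S = cov(lay date, w) with the sample
(n−1) denominator (switchable); the identity
S = (fitness-weighted trait mean − trait mean)·n/(n−1) is used as an
independent oracle in the tests. SEs come from a record-level
non-parametric bootstrap (B ≥ 200 enforced, degenerate resamples skipped
and counted, seeded). Gradients regress w on standardized z and z²;
γ defaults to twice the quadratic coefficient (the Lande–Arnold
convention), with a raw-coefficient mode, because published values do not
always state whether they are doubled. The unit of analysis is the
breeding record (brood); the pipeline also reports the female-season
(annual fitness) version of the differential.

## Power analysis

Replicates simulate a new trait on the *observed* structure (pedigree,
record-to-female/mate/year mapping): gene-dropped breeding values plus
equal-variance PE, mate and year effects (v each, default total/10) and a
residual chosen so that h² (year excluded; V_F = 0, the simulated trait
has no fixed effects) hits the target and the total variance matches the
real trait's scale (~830 days² by default): V_A = h²·(total − v),
V_R = total − 3v − V_A, infeasible allocations raising an error. Each
replicate refits the animal model (default 50,000 iterations — reduced
relative to the real-data protocol, flagged by the ESS warning machinery)
and reports posterior mean/median/mode and 95% interval of h², plus the
fractions of replicates whose mode/median exceed a reference estimate and
the CI coverage of the target.

## The synthetic-data generator

The generator emulates the study conditions end to end: 16 seasons,
carrying capacity of 55 breeding females and 45 males, founders at season
one, overlapping generations, 60% extra-pair paternity, clutches of 3–5
eggs. Lay dates are intercept 60 (late October) + 12.5 d first-year
offset + 1.33 d/yr past age 6 − 1.70 d/mm tarsus + 35 d per additional
clutch + cue effect (−18.28 d/°C on the season's 50-day window mean of a
sinusoid-plus-noise daily temperature series, between-season cue SD
0.4 °C) + residual year noise (SD 5 d) + breeding value + permanent
environment + mate effect + residual, with variance components at the
study's scale (V_A 27, V_PE 46.1, V_Mate 14.6, V_R 161 days²; true
h² ≈ 0.03). Stage survival: egg→hatchling 0.73 flat; hatchling→fledgling
a pure Gaussian curve of lay date (peak 0.82 at day 44, width 76 d,
declining to ≈ 0.12 at the late edge of observed lay dates — a curve
*range*, not an additive floor, so the fitted optimum model is correctly
specified); fledgling→recruit by capacity-driven recruitment with no
lay-date dependence (recruits refill the breeding pools and appear as
breeders in later seasons, making per-clutch fitness consistent with the
pedigree). Reclutching follows a logit in the standardized start date
(slope −1.5, nominal SD 20 d); female survival has a positive
clutch-count effect (0.734) and a mild age decline. One global seed fans
out through a fixed `SeedSequence.spawn` order (demography, temperatures,
phenotypes), so regeneration is byte-identical and component streams are
stable.

What the generator does *not* emulate: actual station temperature
records or management harvests, body condition, density dependence,
immigration, observation error in parentage, and any genotype-by-
environment structure. Passing recovery tests therefore demonstrates
estimator correctness at realistic signal-to-noise under the assumed
models — not robustness to the misspecifications real field data carry.

Focused simulators exist for single analyses: data drawn exactly from
the fitness-curve model (with a movable trait mode to create
mode–optimum discrepancies) and a start-of-season table with the
first-year/flat/late-slope age structure for model-selection tests.

## Numerical choices and conventions

- Posterior mode: binned Gaussian-kernel density (4,096 bins, Silverman
  bandwidth 0.9·min(sd, IQR/1.349)·n^(−1/5) by default, configurable
  multiplier) with quadratic interpolation of the peak. Mode estimates
  inherit the bandwidth; KDE-argmax noise decays slowly (~n^(−2/7)), so
  mode-based comparisons at Silverman bandwidth carry sampling error of a
  few hundredths of an SD even with 10⁶ draws.
- Variance log-parameters are clipped to e^(±12) in the GLMM optimizer —
  a boundary estimate means "zero variance" and keeps the joint Hessian
  invertible for Wald SEs.
- Calendar rendering of season days uses a non-leap reference year; the
  1-day February ambiguity is irrelevant at the reported precision.
- Problem sizes in the test and acceptance runs (chains of 8,000–30,000
  iterations, 10–20 replicates per study) are scaled-down versions of the
  full protocol, chosen so each study still has the power to detect the
  failures it guards against; the full protocol remains the default on
  the estimator classes.

## Known limitations

- The GLMM engine fits random intercepts only — no random slopes, no
  correlated random effects, matching the analyses it serves.
- The Laplace likelihood for binomial/Poisson GLMMs shares the small-
  cluster bias of every single-quadrature fitter (lme4's default).
- The animal model is Gaussian-only, without dominance, maternal-genetic
  or genomic components; skewness in lay date is handled by the clutch-
  number fixed effect rather than a non-Gaussian response.
- Single-site year-effect updates in the optimum sampler can mix slowly
  when a year has very few records; the PSRF table makes this visible.
- Mean pedigree depth depends on the founder convention (0 vs 1); both
  are reported and neither is forced to match any particular published
  value.
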