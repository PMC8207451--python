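# Methods

## The data-generating model

The generator produces single-cohort capture–recapture data for a population
containing mated male–female pairs whose fates are linearly correlated.

**Entities.** Each of the `n` animals gets an i.i.d. fair-coin sex.  Males and
females are mated maximally: with #M males and #F females there are
min(#M, #F) pairs and the majority-sex leftovers stay single, giving
m = n − min(#M, #F) entities (e.g. 105 M / 95 F → 95 pairs + 10 single males,
m = 105).  Pair assignment is randomized inside the replicate's RNG stream;
with homogeneous parameters the assignment is distribution-neutral, but the
randomization keeps the contract honest for heterogeneous extensions.

**Per-interval dynamics.** For each interval t−1 → t, an intact pair first
draws a togetherness indicator d ~ Bernoulli(δ).  Its joint survival outcome
over the four cells (both, female only, male only, neither) has

    P(both) = d · γ · σ_φF σ_φM + φF φM,

the one-survivor cells fixed by the marginals, and σ_φG = sqrt(φG(1−φG)).
The same d conditions the joint recapture draw at occasion t with (pF, pM, ρ).
A pair that lost a member, a single, or a separated pair member draws
independent Bernoulli(φ), Bernoulli(p).  Death (confounded with permanent
emigration, as in any CJS analysis) is absorbing; widows never re-pair.
Everyone is marked and released at occasion 1, so all histories begin with 1.

**Admissible correlations.** For Bernoulli marginals (a, b) the linear
correlation must lie in the Fréchet–Hoeffding band
[−min(√OP, 1/√OP), min(√OR, 1/√OR)] with OP/OR the odds product/ratio.  The
upper bound is 1 exactly when the marginals are equal.  The implementation
verifies these expressions against a brute-force search over the one free
cell of the 2×2 joint table.  Correlations within 1e−10 of a bound are
clamped onto it (grid endpoints such as γ = 1.0 must not fail from float
rounding); anything further out raises, reporting the admissible interval.
Degenerate marginals (0 or 1) have zero variance, so the correlation term
vanishes and the independence product is returned without error.

**Design choices left open by the problem.**

* Separation is redrawn independently every interval; a separated pair may be
  together the next interval.  All reference experiments use δ = 1, which
  makes this choice inert there.
* The same separation draw conditions both the survival interval and the
  recapture event at its end.
* Sexes are redrawn for every replicate (the sex composition is part of the
  sampling variability).
* Reproducibility: replicate k of a run uses the RNG substream spawned as
  child k of the configuration seed; every stochastic routine takes its
  generator explicitly.  Identical seeds give bit-identical output.

## Estimation

The fitter works on the per-sex counts of the 2^(T−1) observable histories.
With constant φ and p the cell probability factorizes into per-interval terms
times the never-seen-again tail χ_t = (1−φ) + φ(1−p)χ_{t+1}, χ_T = 1.  The
four structures {(φ,p), (φG,p), (φ,pG), (φG,pG)} have 2–4 free parameters;
with time-constant parameters there is no terminal-parameter confounding and
all are estimable.

Optimization is quasi-Newton (BFGS) on the logit scale with analytic
gradients, three starting points (neutral logit(0.5), a seen-again-fraction
heuristic, and a fixed random draw), and gradient tolerance 1e−9.  Standard
errors come from the numerically differentiated observed information at the
optimum; 95% intervals are Wald intervals on the logit scale, back-transformed
— the construction whose coverage behaviour the studies measure.  Estimates
within 1e−6 of 0/1 are flagged as boundary fits and kept in all tallies
(their possibly degenerate intervals count as non-covering unless they contain
the truth).  Non-converged fits are returned flagged, not raised.

## Deviance and the variance-inflation factor

The deviance reference is the saturated multinomial over the **observed**
distinct histories: per sex group for any structure with a sex effect, and
over the sexes pooled for (φ,p), which treats the data as one
undifferentiated sample.  Unobserved cells contribute neither to the
saturated likelihood (0·log 0 = 0) nor to the degrees of freedom:

    df_deviance = Σ_saturated groups (#observed histories − 1) − #parameters.

This bookkeeping is deliberate and is the replication-sensitive choice behind
the median-ĉ grid.  At γ = ρ = 1 the data are near-duplicated across sexes;
referred to the pooled saturated model the (φ,p) deviance doubles while its
df does not, driving ĉ = deviance/df toward 2 — the classic
replicated-data signature.  A per-sex saturated reference would instead
absorb the duplication and push ĉ *below* 1, which is what the sex-effect
structures show.  Counting only observed cells matters at these sample sizes
because the rarest history (expected ≈ 1.1 per sex at n = 200) is absent from
a group in a third of replicates.

ĉ is summarized across replicates by its median (the median-ĉ estimator);
the null reference density is χ²_df/df, whose analytic median
(e.g. 0.9454 at df = 12) is available alongside Monte-Carlo draws.  A Pearson
X²/df variant is provided for cross-checking; cells with expected count below
1e−9 are pooled into the never-seen-again cell before the ratio.

The sex-effect likelihood-ratio statistic G² = 2(ℓ_general − ℓ_reduced) is
computed from log-likelihoods directly (so it is independent of the deviance
reference), clamped at 0, and referred to chi-square with the
parameter-count difference as df.  A consequence of the grouping convention:
deviance additivity (dev_reduced − dev_general = G²) holds between structures
sharing the same saturated reference, i.e. among the sex-grouped ones.

## The replicated studies

All studies use the reference conditions n = 200, T = 4, δ = 1,
φF = φM = 0.7, pF = pM = 0.8 and K = 1000 replicates per grid cell
(overridable), with per-cell seeds derived deterministically from the study
seed.

* **Coverage** (ρ = 0): for each γ in −0.4 … 1.0 (step 0.1) and model,
  the survival estimate's mean relative bias B = (mean φ̂ − φ)/φ, mean
  relative 95% interval width R = mean(UB − LB)/φ, and coverage
  C = fraction of intervals containing the true φ (for sex-specific
  structures the female parameter is tracked).
* **LRT calibration** (ρ = 0, γ ∈ {0, 0.3, 0.6, 0.9, 1}): per-replicate G²
  and p-values for (φG,p) vs (φ,p) and (φ,pG) vs (φ,p); rejection rate at
  0.05 and Kolmogorov–Smirnov distances to χ²₁ / U(0,1).
* **ĉ grid** (ρ = 1, same γ grid): per-replicate deviance ĉ for all four
  structures and its median.

## What the synthetic data do and do not show

The generator realizes exactly the stated mechanism: homogeneous parameters,
fair-coin sexes, maximal pairing, single cohort, permanent widowhood.  Real
pair-bonded populations add staggered entry, time- and age-varying rates,
divorce and re-pairing, imperfect knowledge of pair membership, and usually
lower recapture rates — none of which are modeled, so passing studies
demonstrate the *mechanism* (correlation-driven under-coverage, LRT
deflation, and ĉ blindness in group-aware models), not field-data magnitudes.
In particular, at recapture rates well below 0.8 sparsity itself distorts the
deviance distribution and would confound the correlation effect.

## Numerical notes and problem sizes

Tolerances: joint-cell normalization and marginal conservation hold to
1e−12; bound agreement with the brute-force search to 1e−9; MLE location is
verified against a step-1e−3 grid search within 2e−3.  The default test run
reproduces the studies at K = 1000 for the headline cells (a few minutes on
one CPU) with a K = 100 smoke pass for orderings; example scripts use
K = 200 so they finish in seconds.  These sizes are the package's own
choices balancing Monte-Carlo error (median ĉ and coverage move by ≲0.03 at
K = 1000) against wall-clock time.

## Known limitations

* Only the four constant-parameter, sex-structured CJS models are fitted;
  time-dependent structures, covariates, and estimation of (γ, ρ, δ)
  themselves are out of scope (the extended model is a generator here, not a
  fitted model).
* The deviance/df convention above reproduces the behaviour of the standard
  MARK-style pipeline it emulates, but other software may count cells
  differently; ĉ values are comparable only within one convention.
* The `.inp` writer emits one line per individual with male/female group
  columns; pair identity is not representable in that dialect (the CSV
  dialect preserves it).
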