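# Methods

This note documents the models, conventions and numerical choices behind
`aridtrait`, and what the synthetic-data tests do and do not demonstrate
about real assay data.

## The assay model and trait definitions

The package assumes a gravimetric desiccation assay: individuals acclimated
to full hydration, then held without food in dry air and weighed at fixed
daytime clock times until death or a fixed horizon. Time is measured from
the first weighing, so the default schedule is {0, 3, 6, 9} + 24·k hours
(3 h gaps within a day, one 15 h overnight gap) with a 96 h horizon.

Death status is checked at each weighing, never observed exactly. The
survival time of an individual first found dead at time *t₁* after being
alive at *t₀* is the median of the two, (*t₀* + *t₁*)/2, and the wet mass at
death is the mean of the two bracketing masses. The midpoint rule is applied
to every death interval — overnight and within-day alike — for consistency;
the field convention states it only for overnight deaths, but applying it
uniformly changes within-day deaths by at most 1.5 h and removes a special
case. Survivors are censored: DR = horizon/horizon = 1 and the physiological
traits (WLR, WLT, fWC) are undefined, because they are only measured on
individuals that died.

- **DR** = survival_h / horizon_h ∈ (0, 1].
- **WLR**: ordinary least-squares slope of water mass (wet − dry) on time
  over *alive* observations, negated and divided by initial water content
  (first wet mass − dry mass). Units mg mg⁻¹ h⁻¹ (proportion of initial
  water per hour). At least 3 alive observations are required — a 2-point
  slope is noise-dominated — so very fast-dying individuals are excluded
  from modelling, with the reason logged per individual.
- **WLT** = 100 × (initial wet − wet at death)/initial water, in %.
- **fWC** = initial water / dry mass.
- Initial water content uses the first observed wet mass: the acclimation
  protocol guarantees near-maximal hydration at t = 0.
- Wet mass marginally below dry mass (balance noise) is clamped to dry mass
  with a warning; a deficit above 2 % of dry mass at an alive observation is
  treated as a data error. Dead observations are always clamped, since a
  dead individual can legitimately have exhausted its water by the next
  weighing.
- log body mass uses the natural logarithm of dry mass in mg.

The per-species summary reports BM over all individuals (dry mass is
measured post-mortem for everyone) and DR/WLR/WLT/fWC over the dead only.

## Binomial models of desiccation resistance

DR is a proportion of a fixed horizon, so it is modelled as a binomial
count: survived half-hour units out of 192. The 0.5 h unit is chosen so
every survival midpoint (x.5 hours, from the overnight-median rule) maps to
an integer count exactly. The denominator convention affects standard
errors, so it is recorded in the fit metadata of every run.

**GLM (relative effects).** `DR ~ species + scaled WLR + scaled WLT +
scaled BM`, logit link, fitted by iteratively reweighted least squares.
Convergence is declared when the score ‖X′(y − n·p̂)‖∞ < 1e−8 (checked in
tests to 1e−6); standard errors come from the inverse observed information.
A converged fit whose linear predictor exceeds 20 in magnitude (fitted
probabilities within ~2e−9 of 0 or 1) is reported as complete or
quasi-complete separation rather than returned silently. Scaled covariates,
(x − species mean)/species mean, are computed within species over the
individuals entering the model, so within-species means of the scaled
columns are 0 by construction and the species indicators absorb all
between-species location differences. The reference species is
configurable; the first species in sorted order is the default.

**GLMM (general effects).** `DR ~ nesting * log BM + WLR + WLT (+ fWC) +
(1 | species)` with dwellers as the reference guild. The scalar random
intercept per species is integrated out by *adaptive* Gauss–Hermite
quadrature: for each species the integrand is re-centred at the conditional
mode of the random effect (found by a damped Newton iteration, vectorised
across groups) and scaled by the local curvature, then evaluated at 15
Hermite nodes (15 vs 31 nodes changes the log-likelihood by < 1e−6 in
tests; one scalar effect makes quadrature both cheap and more accurate than
a Laplace approximation). The marginal likelihood is maximised over
(β, log σ) by L-BFGS-B, started at the GLM estimates with σ = 0.5 and
log σ bounded in [−8, 5]; a fitted σ below 0.01 is flagged as a boundary
estimate. Setting σ = 0 reproduces the GLM log-likelihood exactly, which is
tested. Fixed-effect standard errors come from the numerical Hessian in β
at the optimum, conditional on σ̂ (the usual mixed-model convention); AIC
counts the fixed effects plus one variance parameter.

Estimates, standard errors and the random-effect SD agree with
`lme4::glmer(..., nAGQ = 15)` to ~1e−4 on simulated data (asserted in the
test suite via Rscript).

**Variance explained.** "Pseudo-R²" is reported as the squared Pearson
correlation between observed and fitted proportions (conditional on the
species modes for the GLMM), with a deviance-based alternative
(1 − (ll − ll₀)/(ll_sat − ll₀), clipped to [0, 1]) printed alongside; the
metric is named in every report because conventions differ.

**Term pruning.** Backward pruning drops candidate terms with joint Wald
p ≥ α (default 0.05), worst first, refitting after each drop. Interaction
terms are eligible before main effects, and a main effect is never dropped
while an interaction involving it remains — so a non-significant
interaction is demoted to additive structure first. The pipeline's default
candidates are fWC and the nesting × log BM interaction; every drop is
recorded in an audit log.

**Wald inference.** p-values are two-sided normal on z = estimate/SE, with
stars at 0.05/0.01/0.001. With few grouping levels (8 species) Wald-normal
intervals on the GLMM run slightly anti-conservative — the variance
parameter is estimated from only 8 levels, so the effective reference
distribution is closer to a t with ~7 df than a normal. Simulation at the
study's scale shows ~95 % coverage for slopes and ~88 % for the intercept;
users needing calibrated intercept intervals at this scale should prefer a
parametric bootstrap (out of scope here).

## Independent contrasts and phylogenetic signal

Contrasts are computed by the classic pruning pass: at each internal node
the standardized contrast is (x᠎ᵢ − xⱼ)/√(vᵢ + vⱼ), the node value is the
1/v-weighted mean of its daughters, and its branch is lengthened by
vᵢvⱼ/(vᵢ + vⱼ). A tree with n tips yields exactly n − 1 contrasts. The
implementation is verified against a brute-force GLS oracle (the quadratic
form x′C⁻¹x minus the phylogenetic-mean term, with C the shared-path-length
matrix) and against `ape::pic`.

Polytomies, unifurcations, and missing or non-positive branch lengths are
rejected at parse time (standardization divides by √v; the intended use is
a small, fully resolved species tree). Trees are read and written as strict
Newick via dendropy.

**Signal statistic.** The variance of the standardized contrasts, computed
as the mean-centred population variance (denominator n). The denominator
and centring conventions rescale observed and null values identically, so
the randomization p-value is invariant to the choice (and to any affine
transformation of the trait — both tested). The null is built by shuffling
trait values across tips with the topology fixed (default 999 shuffles);
the one-tailed p-value is the add-one-corrected proportion of null
variances ≤ observed, since *low* contrast variance indicates that related
species resemble each other. A two-tailed option doubles the smaller tail.
At least 2 contrasts (3 tips) are required; a constant trait is rejected as
degenerate.

**Contrast correlations.** Through-origin correlation
r = Σxy/√(Σx²Σy²) (contrasts have arbitrary sign, so no intercept), with a
parametric p from t = r√((n−1)/(1−r²)) on n − 1 df and an optional
sign-flip randomization p; both are reported because the two can disagree
at small n.

**Nesting strategy as a trait.** When the guild enters a contrast analysis
it is coded ordinally (dweller 0 < tunneler 1 < roller 2). The ordering is
an assumption, flagged in the signal-stage metadata of every run; any other
coding can be passed explicitly.

## The synthetic-data generators

`simulate_assay` is mechanistic: per individual, dry mass, fWC, WLR and WLT
are drawn from per-species normal distributions (redrawn into their valid
ranges), water mass declines *linearly* at WLR × initial water per hour
(linear because the derivation estimates WLR by a linear-regression slope;
an exponential decline is deliberately not the default), and the true death
time is WLT/(100·WLR) hours. Observations are emitted only at schedule
times, masses get optional Gaussian balance noise (default 0 for oracle
tests; 0.1 mg, the balance resolution, in the demo config — the true error
model of the balance is unknown, so Gaussian is a free choice), and death
is recorded only as the alive flag flipping between weighings — forcing all
downstream code through the interval-censoring rules. The demo
configuration fixes species scales (8 species: 4 tunnelers, 3 dwellers,
1 roller; 7–39 individuals each, 137 total; dry mass ~8–250 mg, WLR
0.005–0.018 h⁻¹, WLT 47–71 %) in a YAML file rather than in code.
Within-species CVs for fWC and WLT are optional generator extensions
(default 0) without which the within-species scaled covariates would be
degenerate.

`simulate_tree` draws pure-birth (Yule) trees; `simulate_bm_traits` runs a
Brownian walk along the branches (increment variance σ²·branch length) —
the null process under which standardized contrasts are i.i.d. normal.
`simulate_glmm_dataset` produces binomial responses with standard-normal
covariates and a Gaussian species intercept for parameter-recovery tests.
All generators are bit-reproducible given their seed; the pipeline derives
a separate seed per stage by hashing the stage name into a seed sequence,
so adding a stage never changes another stage's draws.

**What passing tests show — and don't.** On noise-free mechanistic data the
trait derivation recovers ground truth up to schedule discretization only
(survival and death-mass errors bounded by half the death interval; WLR and
fWC exact), so those tests validate the *bookkeeping*, not the biology.
Real assays add balance noise, non-linear late-stage water loss, behaviour
and metabolic variation, none of which the generator emulates; the linear
model is the generator's assumption, matching the derivation's assumption.
GLMM recovery tests show calibration when the random-intercept model is
true — they cannot show robustness to misspecified random-effect
distributions.

## Problem sizes and numerical choices

Simulation-based checks run at the study's own design scale: 8 species with
7–39 individuals (137 total) for assay and model tests, 200 replicates for
coverage, 500 trees of ≤ 8 tips for the contrast/GLS comparison, 500
datasets × 199 shuffles for randomization-test calibration and 100 × 999
for power on 32-tip trees. Key tolerances: IRLS score < 1e−8; GLS/contrast
agreement to 1e−8 relative; quadrature convergence 1e−6; GLMM vs lme4
~1e−4. Degenerate inputs fail loudly: separation, rank deficiency (aliased
columns are named), constant traits, polytomies, < 3 alive weighings, and
empty designs all raise typed errors rather than returning numbers.

## Known limitations

- Gravimetric traits cannot separate cuticular, respiratory and excretory
  water-loss pathways; the package does not try.
- The ordinal coding of nesting strategy imposes an ordering with no
  measurement behind it.
- Wald intervals with 8 grouping levels are mildly anti-conservative for
  the intercept (see above).
- Only a single scalar random intercept is supported — no random slopes,
  crossed effects or non-Gaussian random effects.
- The signal test conditions on the supplied tree; branch-length error and
  topological uncertainty are not propagated.
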