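# Methods

## Estimand

A two-arm trial assigns `A ∈ {0,1}` at baseline. Over discrete intervals
`k = 1..K+1` we observe censoring `C_k`, a competing event `D_k` (e.g. death),
an event of interest `Y_k` (e.g. kidney injury), and time-varying covariates
`L_k`, with baseline covariates `L_0` and the within-interval temporal order
`(C_k, D_k, Y_k, L_k)`. A subject who experiences the competing event without a
prior event of interest can never experience the event of interest afterwards;
both event processes are absorbing.

The treatment is assumed decomposable into two components `A = (A_Y, A_D)`
that coincide in the observed data (`A ≡ A_Y ≡ A_D`) but could, in a future
trial, be assigned separately. The estimands are the counterfactual
cause-specific cumulative incidences

    nu_k(a_Y, a_D) = Pr(Y_{k+1}^{a_Y, a_D} = 1),    k = 0..K,

under elimination of censoring. Contrasts in `a_Y` holding `a_D` fixed are the
`A_Y` separable effects; contrasts in `a_D` holding `a_Y` fixed are the `A_D`
separable effects. The total effect telescopes exactly into the `A_Y`
separable effect under `a_D = 1` plus the `A_D` separable effect under
`a_Y = 0`; the package computes the additivity residual as the correctly
rounded sum of the six signed risks (`math.fsum`), which is identically zero.

Mixed assignments (`a_Y ≠ a_D`) are identified from two-arm data only under
additional conditions: a user-declared partition of the time-varying
covariates into a block `L_D` (receiving direct treatment effects only through
`A_D`) and a block `L_Y` (only through `A_Y`), exchangeability/positivity, and
the dismissible component conditions of the hypothetical four-arm trial. The
package does not check these graphically; it provides an empirical strong
positivity diagnostic, a falsification check for the stronger full-isolation
assumption, and a sensitivity analysis for one specific violation.

## Identification formula and estimators

The plug-in evaluator computes, per assignment,

    nu_k = sum_{s=0}^{k} sum over histories l̄_s of
           hY(s+1 | l̄_s, a_Y) * prod_{j=0}^{s} [ SD(j+1 | l̄_j, a_D)
           * SY(j | l̄_{j-1}, a_Y) * f(l_{Y,j} | l̄_{j-1}, l_{D,j}, a_Y)
           * f(l_{D,j} | l̄_{j-1}, a_D) ]

where hazards condition on remaining uncensored whenever censoring exists.
The outer sum is accumulated recursively over `s`, extending history strata by
the observed support of the fitted saturated covariate densities; an
independent literal transcription of the double sum lives in the test-suite as
an anti-drift oracle and agrees to 1e-12.

Two weighted estimators re-express the same functional: `nu1` averages over
subjects with `A = a_Y`, weighting event terms by a censoring weight, a
cumulative competing-event survival ratio (`a_D` over `a_Y`) and a D-block
propensity-ratio product; `nu2` averages over `A = a_D`, weighting by the
censoring weight, event-of-interest hazard/survival ratios (`a_Y` over `a_D`)
and a Y-block propensity-ratio product. Both estimating equations are linear
in `nu_k`, so the solutions are closed-form weighted means. Under the
degenerate partitions (`L_D = L` for `nu2`, `L_Y = L` for `nu1`) the
propensity-ratio weights are identically one and the simplified variants need
no covariate-distribution modelling.

### Baseline covariates at j = 0

The printed weight products have a `j = 0` factor whose conditioning set is the
baseline covariate vector. The package resolves it by treating `L_0` as the
time-0 D-block (consistent with the assumed within-interval order `L_D` before
`L_Y`): the `j = 0` factor of the Y-block propensity weight then telescopes to
one exactly, the `j = 0` factor of the D-block weight is the baseline
propensity ratio, and the plug-in evaluator standardizes `L_0` to its
empirical distribution in arm `A = a_D`. In the population this choice is
immaterial — randomization makes the baseline distribution identical across
arms — but in finite samples it is exactly what makes the three estimators
coincide. A consequence: the simplified `nu1` retains the baseline propensity
factor (a design-known quantity in a randomized trial); it still requires no
time-varying covariate-distribution models.

### Exact finite-sample equivalences

With saturated nuisance fits (empirical frequencies over full measured
histories) the three estimators agree to machine precision, and with
`a_Y = a_D = a` and no censoring each reduces exactly to the arm-`a` discrete
Aalen–Johansen cumulative incidence. These identities hold whenever the
empirical conditionals are positive on every history stratum the formula
visits — the in-sample analogue of the positivity assumptions (in particular,
a stratum where one arm has at-risk subjects but zero observed events breaks
the `nu2` identity, because a zero hazard enters a weight denominator). The
shipped equality tests therefore use cell sizes at which such degeneracies do
not occur; the estimators raise an explicit positivity error when an undefined
weight would actually be used.

## Nuisance models

Saturated mode conditions on the exact stratum `(arm, L_0, L_1..L_k)` and is
the nonparametric MLE; predictions at never-observed strata raise rather than
impute (strong positivity is an assumption, not a smoothing licence).
Parametric mode fits pooled logistic models over person-time with polynomial
time-varying intercepts (degree `min(3, K)`, which saturates the time
dimension on short grids), baseline covariates and the current interval's
covariates; the event-of-interest hazard is fitted per arm by default.
Square and covariate-by-time terms are available as model terms. Covariate
densities and the baseline distribution are estimated in saturated mode only:
parametric density modelling invites incongenial weight components, and the
package warns whenever both partition blocks are non-empty and the propensity
ratios come from parametric fits. Separation is not penalized by default (MLE
semantics); non-convergence sets a flag and warns.

## Structural simulator

Every mechanism (C, D, Y and each covariate) is Bernoulli through the
inverse-logit of a linear predictor over `a_Y`, `a_D`, baseline covariates,
the previous interval's covariates, same-interval earlier covariates and
optional standard-normal latent variables (`U_{L,Y}`, `U_{L,D}`) that are
never exported. Logistic-linear mechanisms make the pooled logistic nuisance
models correctly specified, isolating estimator logic from misspecification in
tests. Scenario presets fix the arrow structure of the isolation settings:

| preset | structure |
| --- | --- |
| `fig2b` | full isolation: `a_Y → Y`, `a_D → D` only; L a treatment-free common cause |
| `fig4a` | `A_Y` partial isolation: additionally `a_D → L` |
| `fig4b` | `A_D` partial isolation: `a_Y → L` instead |
| `fig5a` | no isolation, shared covariate (both components into the same L) |
| `fig5b` | no isolation, partitioned covariates (`a_D → L_D`, `a_Y → L_Y`) |
| `fig7e` | full isolation + latent causes `U_{L,D}`, `U_{L,Y}` of L and each hazard |
| `fig7f` | `A_Y` partial isolation + latent `U_{L,Y}` into L and the Y hazard |
| `fig8a` | `fig4a` structure plus a baseline covariate and covariate-dependent censoring |
| `fig8a_heavycens` | same with strong covariate-dependent censoring (≈65% censored) |
| `null` | no treatment arrows anywhere |

Default follow-up is three intervals (`K_plus_1 = 3`) with binary covariates.
Coefficients are fixed study conditions chosen once at trial-realistic
magnitudes: per-interval event-of-interest hazards rising from ≈8% to ≈12%
(logit intercepts −2.4 to −2.0), competing-event hazards ≈10–12%, protective
component effects of −0.7 (`a_Y → Y`) and −0.8 (`a_D → D`) on the logit scale,
covariate prognostic effects of 1.0–1.2, treatment-into-covariate arrows of
1.0–1.2, and latent effects of 1.0–1.2 in the unmeasured-confounding presets
(strong confounding, by design, so the sensitivity machinery has something to
correct). Arrows from `D_k` into later `Y` are omitted: among at-risk histories
the competing-event determinism makes them vacuous in this discrete setting.

Randomness is one uniform matrix with a fixed column layout drawn from the
master seed, so two-arm and four-arm runs with the same seed share every draw:
setting `A_Y = A_D = a` in the four-arm design reproduces the two-arm outcome
path subject by subject, and censored/uncensored runs with the same seed are
subject-aligned (used by the paired censoring-correction analyses). Ground
truth `true_risk` is Monte Carlo with the censoring hazard forced to zero
(default 10^6 draws; the tests also check it against exact path enumeration).

What the simulator does **not** emulate: continuous or high-dimensional
covariates, irregular visit schedules, measurement error, time-varying
treatment, semi-competing follow-up after the event of interest, or
non-logistic outcome processes. Passing tests therefore demonstrate estimator
correctness under correctly specified discrete-data mechanisms, not robustness
to the misspecifications real data impose.

## Sensitivity analysis

The selection-bias function `t_k(l̄_k, a_Y)` is the difference between the
four-arm Y-hazards at `(a_Y, a_D = 0)` and `(a_Y, a_D = 1)` given measured
history; it is identically zero under the relevant dismissible component
condition and is identified by a four-arm experiment (the simulator tabulates
this oracle empirically). The corrected estimator `nu2†` shifts each numerator
hazard by `(−1)^{a_D} t`; the corresponding survival factors use the
complement of the shifted hazard, `1 − (h_Y + (−1)^{a_D} t)`, keeping event and
survival factors internally consistent (a literal reading that adds the term
to the survival factor is available behind `literal_survival_shift=True`).
Shifted factors outside `[0, 1]` are clipped and counted; the clip count is
reported because silent clipping would mask extreme `λ`. Shipped families are
the constant `t_k = λ` and the linear-in-k `t_k = λ·k/(K+1)`; sweeps report the
`λ` at which the end-of-follow-up effect crosses zero when the grid brackets
it. Analogous sensitivity functions for the remaining dismissible component
conditions are not implemented.

The falsification check compares the baseline-covariate-only estimator (the
restricted full-isolation analysis, all conditioning sets using `L_0`) with
the time-varying-adjusted estimator and flags any per-interval bootstrap
|z| ≥ 3 across the mixed assignments.

## Inference

Bootstrap resamples subjects with replacement (preserving serial structure),
refits all nuisance models per resample, and reports percentile intervals
(the interval type is a package choice; analytic variances are out of scope).
`B` defaults to 500; per-resample seeds are spawned from the master seed so any
single resample is reproducible. Failed resamples (positivity or estimation
errors) are excluded and counted, with a warning above 10%.

## Problem sizes in the shipped analyses

The acceptance computations use: n = 2,000 for the exact-equality and
bootstrap-coverage studies (200 replicates × B = 200), n = 200,000 for the
two-arm versus four-arm recovery, n = 100,000 (with 2×10^6 four-arm draws for
the oracle `t` and 10^6 for ground truth) for the sensitivity and censoring
studies, and n = 20,000 with B = 150–200 for the falsification check. These
sizes were chosen so that Monte-Carlo error is small relative to the effects
being measured while each analysis completes in seconds to a few minutes on
one CPU.

## Numerical choices and degenerate inputs

Covariate histories are encoded as mixed-radix integer codes (D-block before
Y-block within an interval), so density supports and conditional lookups are
sorted-array searches. Structurally missing values use the sentinel −1 and are
distinguished from unexpected missingness by the validator. Empty treatment
arms raise estimation errors; cohorts without time-varying covariates are
fully supported (the density factors drop out); a lambda grid for sensitivity
sweeps must contain 0. Weight diagnostics (per-interval mean, max, effective
sample size) are computed on exactly the weights used. Weight truncation is
available nowhere: extreme weights are surfaced, not capped.

## Known limitations

- Discrete time and discrete (finite-support) covariates only; continuous
  covariates disable saturated estimation and the g-formula evaluator.
- No efficient-influence-function or doubly robust estimators, no
  machine-learning nuisance fitting, no cross-fitting.
- No time-varying treatments; a single baseline treatment decomposition into
  exactly two binary components.
- The congeniality of parametric propensity-ratio weights is warned about,
  not solved; the alternative joint-density weighting is not implemented.
- Identification conditions themselves are assumptions; the package can
  falsify full isolation and probe one dismissible component condition, but
  cannot verify identification.
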