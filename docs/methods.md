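# Methods

## Scientific setting

`netgradient` studies how area-level social deprivation shapes *net*
survival after cancer — survival from the cancer itself, separated from
other-cause mortality — in the situation typical of population-based
registries: no cause of death, a continuous deprivation score (an EDI-like
index) attached to each patient's residence area, and national life tables
that describe background mortality by age, calendar year, sex and region.

The observed mortality hazard of a patient is decomposed as

    h(t, a, EDI, z) = hE(t, a, EDI) + hP(a + t, z),

where `t` is time since diagnosis, `a` age at diagnosis, `hE` the excess
mortality hazard attributable (directly or indirectly) to the cancer, and
`hP` the known background hazard looked up in a life table at the attained
age and time-updated calendar year for the patient's sex and region.
Net survival is `S_N(t) = exp(-∫₀ᵗ hE du)` and the effect measure is the
excess hazard ratio (EHR) between two EDI values at a given time and age.

## Model

`log hE` is a sum of penalized spline terms; four nested structures encode
the scientific hypotheses about the deprivation effect:

| structure | formula | interpretation |
|---|---|---|
| M0  | tensor(t, a) | no EDI effect |
| M1  | tensor(t, a) + s(EDI) | effect constant over time and age |
| M1b | tensor(t, a) + s(EDI) + tint(t, EDI) | time-dependent effect |
| M2  | tensor(t, a, EDI) | time- and age-dependent effect |

plus a degenerate `constant` (intercept-only) structure kept for
diagnostics; it reduces the model to the exponential distribution and has a
closed-form MLE, which several tests exploit.

### Splines and penalties

One-dimensional smooths are restricted (natural) cubic splines in the
truncated-power parameterization: `k` knots give `k-1` columns (`x` plus
`k-2` nonlinear functions), cubic between the boundary knots and exactly
linear outside them, with the nonlinear pieces scaled by the squared knot
range for conditioning. The roughness penalty is the *exact* integral of
products of second derivatives (the second derivatives are piecewise
linear, so per-interval Simpson integration is exact); a linear function is
always in the penalty null space, which means a purely log-linear EDI
effect is never shrunk — important for unbiased EHR recovery.

Knot counts are 6 for time, 5 for age, 5 for EDI, placed at equally spaced
percentiles of each variable's distribution *among deceased patients*
(events carry the information about the hazard). No winsorization is
applied to the long right tail of EDI.

Tensor products use the row-wise Kronecker product of marginal bases, each
margin augmented with a constant column so marginal main effects are
spanned; the resulting duplicate constant (the product of the two constant
columns) is dropped and the remaining columns are centered. Each tensor
carries one penalty per margin: the marginal curvature penalty
Kronecker-embedded with identities on the other margins. Column ordering is
fixed — the first margin (time) varies fastest.

Identifiability constraints are implemented by *exact centering with
respect to a fixed uniform 101-point grid over the knot span* (equivalent
to projecting out the constant, but closed-form and data-independent).
The interaction-only tensor `tint(t, EDI)` uses grid-centered margins: each
column is a product of two functions that both average to zero over their
own coordinate's grid, so the span contains no function of `t` alone nor
of `EDI` alone — the functional-ANOVA constraint. `tint` carries two
smoothing parameters (one per direction), so M1b has five in total
(two for tensor(t,a), one for s(EDI), two for tint).

### Likelihood

The full likelihood uses `hP` as a known additive offset at event times;
the background cumulative hazard is parameter-free and omitted:

    ℓ(β) = Σᵢ [ δᵢ log(hEᵢ(tᵢ) + hPᵢ) − ∫₀^{tᵢ} hEᵢ(u) du ] − ½ Σⱼ λⱼ βᵀSⱼβ.

The integral is Gauss–Legendre quadrature per subject (default 20 nodes;
near machine precision for smooth log-hazards — verified against closed
forms and dense Simpson oracles). The event term is computed as
`logaddexp(η, log hP)` for stability.

With `hP = 0` the log-likelihood is globally concave. With `hP > 0` the
event term `log(e^η + hP)` is *convex* in the linear predictor, so global
concavity is not guaranteed — a known feature of excess-hazard likelihoods.
In practice the quadrature term dominates near the optimum; the inner
Newton–Raphson uses step halving and a ridge fallback on the penalized
Hessian, and converges when the penalized gradient max-norm falls below
1e-6 and the relative objective change below 1e-9.

### Smoothing selection (LAML)

Smoothing parameters maximize the Laplace approximate marginal likelihood

    LAML(λ) = ℓ_p(β̂_λ) + ½ log|S_λ|₊ − ½ log|H_p| + (M_p/2) log 2π,

with `S_λ = Σ λⱼSⱼ`, `|·|₊` the generalized determinant over the penalized
subspace (rank computed once from the total penalty), `H_p` the negative
penalized Hessian at the inner optimum and `M_p` the null-space dimension.
The outer optimization is L-BFGS-B on `log λ` with forward-difference
gradients, warm-started inner Newton solves, box bounds `λ ∈ [1e-4, 1e8]`,
and multistart from common values {0.1, 10} (a single start and a reduced
iteration cap are used inside large replicate studies; the selected
structure is insensitive to this in the regimes exercised here).

### Structure choice

Structures are compared by corrected AIC,

    AICc = −2 ℓ(β̂) + 2 EDF + 2 EDF (EDF+1) / (n_events − EDF − 1),

with `ℓ` the *unpenalized* log-likelihood at the penalized optimum,
`EDF = tr(H_unpen H_p⁻¹)` the effective degrees of freedom, and `n` taken
as the number of events, which carry the information in survival data
(plain AIC is available behind a flag; which small-sample correction the
original literature intends is not fully determined, so both are kept and
the default is documented rather than asserted). Ties break toward the
simpler structure in the order M0 < M1 < M1b < M2; non-converged
structures are excluded with a warning.

## Predictions and intervals

Net survival, its 95% interval (Wald on the log-cumulative-hazard scale,
z = 1.959964) and EHRs (delta method on the log-hazard difference, using
the inverse negative penalized Hessian as posterior covariance) are
reported at a reference age of 70 and at the national quintile medians of
EDI: mQ1 = −4.2 (least deprived), mQ2 = −2.4, mQ3 = −0.9, mQ4 = 0.8,
mQ5 = 5.1 (most deprived). Time-constant structures produce one EHR row
per quintile; time-dependent structures report 1 month, 1 year and 5
years. Smoothing-parameter uncertainty is *not* propagated into the
intervals by default; the empirical coverage of the resulting CIs is
checked by simulation (~93–96% in the recovery study).

## Pohar-Perme benchmark

The non-parametric benchmark weights each subject's counting process by
the inverse of its own expected survival `1/S_{P,i}(t)`, computed exactly
from the piecewise-constant life-table hazard. Between consecutive
observed times the weighted population-hazard integral has a closed form:
because `w_i' = hP_i w_i`, the integrand is the logarithmic derivative of
the weighted at-risk sum `W(u)`, so each interval contributes exactly
`log W(b)/W(a)`. The event jumps are removed in product-limit form by
default, so with unit expected survival the estimator *equals*
Kaplan–Meier; the classical `exp(−dN^w/Y^w)` form is available via
`jump_form="exp-cumhaz"`. Model adequacy compares the *population-averaged*
model curve (mean of individual predicted `S_N` over the cohort) with the
Pohar-Perme curve, since the latter is a marginal estimand.

## Synthetic cohorts

The generator emulates a French registry extract: diagnoses uniform over
1 Jan 2006 – 31 Dec 2009, administrative censoring on 30 June 2013, 2%
uniform loss to follow-up, truncated-normal ages (default mean 70, sd 10,
range 30–95), 55% male, two regions. The EDI stand-in is a shifted
log-normal `−16 + LogNormal(log 15.1, 0.25)`: median −0.9, support within
(−16, 56), quintile medians ≈ (−5.0, −2.7, −0.9, 1.2, 4.8), close to the
published national values. National quintile cuts come from the analytic
law (not the cohort draw) and are stored with each cohort. Survival times
are drawn by numerical inversion of the cumulative *total* hazard
`hE + hP` on a daily grid (1/365.25 y) with linear interpolation — exact
for the piecewise-constant `hP` up to daily resolution — processed in
10-year segments so long horizons never materialize a huge grid.
Zero survival times receive the registry convention of 0.5 day.

The true excess hazard is Weibull (default shape 0.9, scale 11 y — about
60% net survival at 5 years, in the range of colorectal cancer) times a
log-linear age effect (0.02 per year around 70) times the deprivation
term: `null` (no effect), `proportional` (default log-EHR 0.024 per EDI
unit, i.e. EHR(mQ5 vs mQ1) = exp(0.024 × 9.3) ≈ 1.25, the order of the
published colorectal gradients), or `time_dependent`
(`β(t) = β₀ e^{−t}`, default β₀ = 0.15: EHR(mQ5 vs mQ1) ≈ 4 at diagnosis,
≈ 1 by five years — a deliberately strong early effect).

The synthetic national life table is Gompertz, `hP = c_sex e^{0.10·age}`
with c calibrated to French-like levels (male ≈ 0.02/yr at 70), a −1%/yr
calendar trend and a 5% region contrast. Deprivation-stratified tables
multiply the base rates by quintile rate ratios, default
(0.70, 0.85, 1.00, 1.20, 1.45) — a deliberately strong gradient in the
spirit of the "extreme correction" sensitivity analyses built from English
deprivation-specific tables; equal-weight renormalization (so the quintile
mean reproduces the base rate) is available behind a flag since published
descriptions do not settle whether the simulated tables preserved overall
mortality.

What the generator does **not** emulate: site-specific biology, cohort
effects in the excess hazard, spatial correlation of EDI, informative
censoring, or registry data-quality artifacts. Passing tests therefore
demonstrate internal statistical correctness of the estimators under a
known data-generating process, not agreement with any particular cancer
site's published estimates.

## Verification studies and problem sizes

`netgradient.studies` packages the self-checks; the test suite and
`scripts/acceptance.py` both drive them. Study sizes were chosen as a
compromise between Monte-Carlo precision and a desktop-scale runtime:

* quadrature and likelihood-derivative checks: closed forms, dense Simpson
  oracles, central finite differences (20 instances, n = 200);
* exponential reduction: intercept-only MLE vs `d/T`; saturated-flexibility
  M0 (λ = 1e-3) vs Kaplan–Meier on the 5-year reporting horizon, n = 1000;
* EHR recovery: proportional scenario, n = 2000 per replicate, 100
  replicates (60 in the acceptance script), mean EHR and 95%-CI coverage;
* structure selection: n = 800 per replicate, 25 replicates per scenario
  (20 in the script), reduced quadrature (12 nodes), single LAML start;
* sensitivity mechanism: n = 2500 per replicate (older cohort, mean age
  75, where background mortality is large enough for the spurious gradient
  to be well separated from estimation noise), 25 replicates;
* determinism: two full pipeline runs at n = 500, hash-compared summaries.

## Numerical choices and edge cases

* Time unit: years of 365.25 days everywhere; decimal calendar years are
  `year + day_offset/365.25`.
* Life-table lookups floor age and year and clamp to the table edges
  (standard practice; keeps the very old in the analysis).
* β initialization: zeros with the intercept at `log(d/T)`.
* `hE + hP = 0` at an event time yields a −∞ log-likelihood which the step
  halving rejects; degenerate knot sets (too few distinct event values)
  raise a validation error; a cohort with fewer than 50 events is refused
  for structure selection.
* Values exactly at a quintile cut are assigned to the upper quintile.
* Extrapolation beyond the last time knot warns and applies the spline's
  linear-tail behavior.

## Known limitations

* Smoothing-parameter uncertainty is ignored in the intervals (flagged
  above); coverage is verified by simulation rather than theory.
* The likelihood is not globally concave when hP > 0; the optimizer is
  robust in the regimes tested but a certificate of global optimality is
  not available.
* The Pohar-Perme variance is a Poisson-type approximation, adequate for
  overlay plots, not for formal inference.
* The deprivation quintile rate ratios used for stratified life tables are
  a calibration, not an estimate of any country's actual gradient.
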