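# netgradient

Flexible excess-hazard modeling of social gradients in cancer **net
survival**, for biostatisticians and cancer-registry epidemiologists.

Population-based registries rarely know the cause of death. Net survival —
survival from the cancer itself — is still estimable by decomposing the
observed hazard into an excess part and the background mortality of the
matched general population:

```
h(t, a, EDI, z) = hE(t, a, EDI) + hP(a + t, z)
```

where `hE` is the excess mortality hazard, `hP` comes from national life
tables (age × year × sex × region), and EDI is a continuous area-level
deprivation score. `log hE` is modeled with multidimensional **penalized
restricted-cubic-spline** terms; four nested structures encode the
hypotheses about deprivation:

* **M0** `tensor(t,a)` — no EDI effect
* **M1** `tensor(t,a) + s(EDI)` — effect constant over time and age
* **M1b** `tensor(t,a) + s(EDI) + tint(t,EDI)` — time-dependent effect
* **M2** `tensor(t,a,EDI)` — time- and age-dependent effect

Coefficients maximize the penalized likelihood (background hazard as a
known offset, Gauss–Legendre quadrature for the cumulative hazard);
smoothing parameters maximize the Laplace approximate marginal likelihood
(LAML); the structure is selected by corrected AIC on effective degrees of
freedom. Results are reported as net-survival curves and **excess hazard
ratios** (EHR) at the national quintile medians of EDI
(mQ1 = −4.2 … mQ5 = 5.1) for a 70-year-old, with delta-method 95% CIs.
A **Pohar-Perme** estimator (inverse-expected-survival weighting, exact
closed-form population term) provides the non-parametric adequacy check,
and deprivation-stratified life tables support sensitivity analyses.
Because real registry data are confidential, the package ships a
synthetic-cohort generator with known truth; every estimator is validated
by parameter recovery. See `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
from netgradient import (make_gompertz_lifetable, select_structure,
                         compute_ehr, predict_net_survival)
from netgradient.cohort import ScenarioConfig, generate_cohort

lifetable = make_gompertz_lifetable()          # synthetic national table
cfg = ScenarioConfig(n_subjects=2000, seed=102,
                     effect_kind="proportional", beta_edi=0.024)
cohort = generate_cohort(cfg, lifetable)       # truth: EHR(mQ5 vs mQ1)=1.25

sel = select_structure(cohort.df, lifetable, starts=(1.0,), outer_maxiter=8)
print(sel.selected)                            # -> M1
row = compute_ehr(sel.best).rows.query("quintile == 5").iloc[0]
print(f"EHR(mQ5 vs mQ1) = {row.ehr:.2f} [{row.ci_low:.2f}, {row.ci_high:.2f}]")
#  -> EHR(mQ5 vs mQ1) = 1.39 [1.15, 1.68]
s5 = predict_net_survival(sel.best, 70.0, 5.1, [5.0]).survival[0]
s1 = predict_net_survival(sel.best, 70.0, -4.2, [5.0]).survival[0]
print(f"5-year net survival: mQ1 {s1:.2f} vs mQ5 {s5:.2f}")
```

The selected structure, M1, says the deprivation effect is real but
constant over follow-up and age; the estimated EHR of 1.39 (CI 1.15–1.68)
is one cohort's draw around the generating truth 1.25 — across 100
replicates the mean estimate is ≈1.24 with ~93–96% CI coverage (see the
acceptance studies below).

### Analysis walkthrough

`analysis/` holds numbered drivers that run the whole pipeline on three
synthetic cohorts (null / proportional / time-dependent deprivation
effect) and write tables and figures under `results/`:

```bash
python analysis/01_simulate_cohorts.py    # cohorts + life tables
python analysis/02_select_structure.py    # M0-M2 fits, AICc table
python analysis/03_predict_gradient.py    # net survival + EHR per quintile
python analysis/04_adequacy_check.py      # model vs Pohar-Perme overlay
python analysis/05_lifetable_sensitivity.py  # stratified life tables
```

Typical step-5 output, demonstrating the attenuation mechanism (a cohort
whose deprivation gradient lives entirely in *background* mortality):

```
background-only gradient, common table: EHR(mQ5 vs mQ1) 1.29 [1.10, 1.52]
background-only gradient,   stratified: EHR(mQ5 vs mQ1) 1.06 [0.89, 1.26]
```

A `netgradient` CLI wraps the same pipeline
(`netgradient simulate/fit/check/run --help`).

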