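"""Structure selection, net-survival / EHR prediction, and adequacy checks.

Predictions are displayed, following common registry practice, at a
reference age of 70 and at the median EDI value of each national
deprivation quintile (mQ1 = -4.2 least deprived ... mQ5 = 5.1 most
deprived).  The excess hazard ratio (EHR) of mQk versus mQ1 is the ratio of
model excess hazards at those two EDI values; when the selected structure is
time-dependent it is reported at 1 month, 1 year and 5 years of follow-up.

The non-parametric benchmark is the Pohar-Perme estimator, with counting
processes weighted by inverse individual expected survival; its jump
component uses the product-limit form by default, so with unit expected
survival it reduces exactly to Kaplan-Meier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, CoverageError, ValidationError
from .hazard_model import (
    FittedModel,
    ModelSpec,
    STRUCTURES,
    optimize_laml,
)
from .lifetables import LifeTable, cumulative_expected_hazard

__all__ = [
    "QuintileMedians",
    "NetSurvivalCurve",
    "EHRTable",
    "SelectionResult",
    "select_structure",
    "predict_net_survival",
    "compute_ehr",
    "pohar_perme",
    "adequacy_check",
    "sensitivity_rerun",
    "drop_missing_edi",
]

Z95 = 1.959964
DEFAULT_EHR_TIMES = (1.0 / 12.0, 1.0, 5.0)
REFERENCE_AGE = 70.0


@dataclass(frozen=True)
class QuintileMedians:
    """Median EDI per national deprivation quintile (evaluation points)."""

    values: tuple = (-4.2, -2.4, -0.9, 0.8, 5.1)

    def __post_init__(self):
        if np.any(np.diff(self.values) <= 0):
            raise ValidationError("quintile medians must be strictly increasing")

    def __getitem__(self, k: int) -> float:
        return self.values[k - 1]


@dataclass
class NetSurvivalCurve:
    time: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    age: float | None = None
    edi: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "net_survival": self.survival,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


@dataclass
class EHRTable:
    rows: pd.DataFrame  # columns: time, quintile, edi, ehr, ci_low, ci_high
    reference_age: float = REFERENCE_AGE

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


@dataclass
class SelectionResult:
    fits: dict
    selected: str
    table: pd.DataFrame

    @property
    def best(self) -> FittedModel:
        return self.fits[self.selected]


def drop_missing_edi(cohort_df: pd.DataFrame):
    """Complete-case rule: drop records with missing EDI, report the count."""
    missing = cohort_df["edi"].isna()
    return cohort_df.loc[~missing].copy(), int(missing.sum())


def select_structure(cohort, lifetable: LifeTable, structures=STRUCTURES,
                     min_events: int = 50, n_quad: int = 20,
                     aic_variant: str = "aicc", **fit_opts) -> SelectionResult:
    """Fit each candidate structure and select by corrected AIC.

    Ties are broken toward the simpler structure (M0 < M1 < M1b < M2), and a
    structure that fails to converge is excluded with a warning.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    df, n_missing = drop_missing_edi(df)
    n_events = int(df["event"].sum())
    if n_events < min_events:
        raise ValidationError(f"only {n_events} events (< {min_events})")
    fits, rows = {}, []
    for structure in structures:
        spec = ModelSpec.from_cohort(structure, df, n_quad=n_quad,
                                     aic_variant=aic_variant)
        try:
            fit = optimize_laml(spec, df, lifetable, **fit_opts)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"structure {structure} failed to converge: {exc}")
            continue
        if not fit.converged:
            warnings.warn(f"structure {structure} flagged non-converged; excluded")
            continue
        fits[structure] = fit
        rows.append({"structure": structure, "aicc": fit.aicc, "aic": fit.aic,
                     "edf": fit.edf, "loglik": fit.loglik, "laml": fit.laml,
                     "n_events": fit.n_events})
    if not fits:
        raise ConvergenceError("all candidate structures failed to converge")
    table = pd.DataFrame(rows)
    key = "aicc" if aic_variant == "aicc" else "aic"
    best, best_val = None, np.inf
    for structure in structures:  # order encodes the tie-break
        if structure in fits and fits[structure].criterion < best_val - 0.0:
            if best is None or fits[structure].criterion < best_val:
                best, best_val = structure, fits[structure].criterion
    table["selected"] = table["structure"] == best
    table.attrs["n_missing_edi"] = n_missing
    return SelectionResult(fits, best, table)


def _cumhaz_with_gradient(fit: FittedModel, t, age, edi, n_nodes=None):
    """Cumulative excess hazard and its gradient in beta at each t."""
    from numpy.polynomial.legendre import leggauss

    n_nodes = n_nodes or fit.spec.n_quad
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x, w = leggauss(n_nodes)
    tq = 0.5 * t[:, None] * (x[None, :] + 1.0)
    wq = 0.5 * t[:, None] * w[None, :]
    a_rep = np.full(tq.size, age, dtype=float)
    e_rep = None if edi is None else np.full(tq.size, edi, dtype=float)
    X = fit.spec.design_matrix(tq.ravel(), a_rep, e_rep)
    lam = np.exp(X @ fit.beta).reshape(tq.shape)
    cum = np.sum(wq * lam, axis=1)
    grad = ((wq * lam).ravel()[:, None] * X).reshape(t.size, n_nodes, -1).sum(axis=1)
    return cum, grad


def predict_net_survival(fit: FittedModel, age: float, edi, time_grid,
                         alpha: float = 0.05) -> NetSurvivalCurve:
    """Model net survival S_N(t) = exp(-int hE) with delta-method 95% CI.

    The interval is Wald on the log-cumulative-hazard scale using the
    posterior covariance of the coefficients.
    """
    t = np.atleast_1d(np.asarray(time_grid, dtype=float))
    if np.any(t < 0):
        raise ValidationError("time grid must be >= 0")
    kmax = fit.spec.knots_time.values[-1]
    if np.any(t > kmax * 1.001):
        warnings.warn("extrapolating beyond the last time knot; "
                      "linear-tail behavior of the spline applies")
    edi_val = None if fit.spec.structure in ("M0", "constant") else edi
    pos = t > 0
    cum = np.zeros_like(t)
    se_log = np.zeros_like(t)
    if pos.any():
        c, grad = _cumhaz_with_gradient(fit, t[pos], age, edi_val)
        cum[pos] = c
        var = np.einsum("ij,jk,ik->i", grad, fit.cov, grad)
        se_log[pos] = np.sqrt(np.maximum(var, 0.0)) / np.maximum(c, 1e-300)
    z = Z95 if alpha == 0.05 else float(-_norm_ppf(alpha / 2.0))
    s = np.exp(-cum)
    low = np.exp(-cum * np.exp(z * se_log))
    high = np.exp(-cum * np.exp(-z * se_log))
    return NetSurvivalCurve(t, s, low, high, age=age, edi=edi)


def _norm_ppf(q):
    from scipy.stats import norm

    return norm.ppf(q)


def compute_ehr(fit: FittedModel, age: float = REFERENCE_AGE, times=None,
                medians: QuintileMedians = QuintileMedians()) -> EHRTable:
    """Excess hazard ratios mQk vs mQ1 with delta-method 95% CIs.

    For time-constant structures (M0, M1) a single row per quintile is
    produced (the ratio does not depend on t); for M1b/M2 the default report
    times are 1 month, 1 year and 5 years.
    """
    structure = fit.spec.structure
    time_constant = structure in ("constant", "M0", "M1")
    if times is None:
        times = (1.0,) if time_constant else DEFAULT_EHR_TIMES
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if time_constant:
        times = times[:1]
    rows = []
    m1 = medians[1]
    for t in times:
        t_label = np.nan if time_constant else float(t)
        for k in range(1, 6):
            mk = medians[k]
            if k == 1 or structure in ("M0", "constant"):
                ehr, lo, hi = 1.0, 1.0, 1.0
                if k == 1:
                    pass
                rows.append({"time": t_label, "quintile": k, "edi": mk,
                             "ehr": ehr, "ci_low": lo, "ci_high": hi})
                continue
            x1 = fit.spec.design_matrix(np.array([t]), np.array([age]),
                                        np.array([mk]))[0]
            x0 = fit.spec.design_matrix(np.array([t]), np.array([age]),
                                        np.array([m1]))[0]
            d = x1 - x0
            log_ehr = float(d @ fit.beta)
            se = float(np.sqrt(max(d @ fit.cov @ d, 0.0)))
            rows.append({"time": t_label, "quintile": k, "edi": mk,
                         "ehr": np.exp(log_ehr),
                         "ci_low": np.exp(log_ehr - Z95 * se),
                         "ci_high": np.exp(log_ehr + Z95 * se)})
    return EHRTable(pd.DataFrame(rows), reference_age=age)


# ---------------------------------------------------------------------------
# Pohar-Perme estimator
# ---------------------------------------------------------------------------

def _expected_cumhaz_matrix(df: pd.DataFrame, lifetable: LifeTable, times):
    """Lambda_P,i(t_j) for every subject i and time t_j (exact, piecewise linear)."""
    out = np.empty((len(df), len(times)))
    for i, (_, rec) in enumerate(df.iterrows()):
        out[i] = cumulative_expected_hazard(rec, lifetable, times)
    return out


def pohar_perme(cohort, lifetable: LifeTable, time_grid=None,
                jump_form: str = "product-limit") -> NetSurvivalCurve:
    """Non-parametric net survival with inverse-expected-survival weights.

    The estimator accumulates, between consecutive observed times, the
    weighted population hazard term exactly (it is the logarithmic derivative
    of the weighted at-risk sum, so each interval contributes
    ``log W(b)/W(a)`` in closed form) and removes the weighted event jumps
    either as a product-limit (default; reduces to Kaplan-Meier when hP = 0)
    or as ``exp(-dN^w/Y^w)`` (``jump_form='exp-cumhaz'``).

    A greenwood-style variance yields pointwise 95% CIs.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    if len(df) == 0:
        raise ValidationError("empty cohort")
    t_obs = df["time_years"].to_numpy(dtype=float)
    delta = df["event"].to_numpy(dtype=int)
    uniq = np.unique(t_obs)
    cum_p = _expected_cumhaz_matrix(df, lifetable, uniq)   # (n, m)
    weights = np.exp(cum_p)                                # 1 / S_P,i(t_j)

    surv = np.empty(uniq.size)
    var_accum = 0.0
    var = np.empty(uniq.size)
    s = 1.0
    prev_t = 0.0
    prev_cum = np.zeros(len(df))
    for j, tj in enumerate(uniq):
        at_risk = t_obs >= tj
        if not at_risk.any():
            surv[j:] = np.nan
            var[j:] = np.nan
            warnings.warn("weighted at-risk set exhausted; curve truncated")
            break
        w_end = weights[at_risk, j]
        w_start = np.exp(prev_cum[at_risk])
        W_end, W_start = w_end.sum(), w_start.sum()
        s *= W_end / W_start                               # exp(+int pop term)
        dying = at_risk & (t_obs == tj) & (delta == 1)
        dN_w = weights[dying, j].sum()
        if jump_form == "product-limit":
            s *= max(1.0 - dN_w / W_end, 0.0)
        else:
            s *= np.exp(-dN_w / W_end)
        if dying.any():
            var_accum += np.sum(weights[dying, j] ** 2) / W_end**2
        surv[j] = s
        var[j] = var_accum
        prev_t = tj
        prev_cum = cum_p[:, j]
    se = np.sqrt(var)
    with np.errstate(invalid="ignore"):
        low = surv * np.exp(-Z95 * se)
        high = surv * np.exp(Z95 * se)
    curve = NetSurvivalCurve(uniq, surv, np.minimum(low, 1.0), np.minimum(high, 1.0))
    if time_grid is not None:
        tg = np.atleast_1d(np.asarray(time_grid, dtype=float))
        step = lambda arr: np.concatenate([[1.0], arr])
        knots = np.concatenate([[0.0], uniq])
        idx = np.clip(np.searchsorted(knots, tg, side="right") - 1, 0, uniq.size)
        sv = step(surv)[idx]
        lo = step(low)[idx]
        hi = step(high)[idx]
        curve = NetSurvivalCurve(tg, sv, lo, hi)
    return curve


@dataclass
class AdequacyReport:
    time: np.ndarray
    model_curve: np.ndarray
    pp_curve: np.ndarray
    sup_distance: float
    pointwise: pd.DataFrame
    comparable: bool = True


def population_averaged_net_survival(fit: FittedModel, cohort, time_grid):
    """Mean of individual model net-survival curves over the cohort.

    This marginal curve is the model-side analogue of the Pohar-Perme
    estimand and is what Table-1-style "population net survival" cells show.
    """
    from scipy.integrate import cumulative_trapezoid

    df = cohort.df if hasattr(cohort, "df") else cohort
    t = np.atleast_1d(np.asarray(time_grid, dtype=float))
    fine = np.unique(np.concatenate([[0.0], t, np.arange(0.0, t.max() + 1e-9, 1 / 24.0)]))
    ages = df["age"].to_numpy(dtype=float)
    edis = df["edi"].to_numpy(dtype=float) if fit.spec.structure not in (
        "M0", "constant") else None
    s_sum = np.zeros(fine.size)
    for start in range(0, len(df), 500):
        sl = slice(start, min(start + 500, len(df)))
        nb = sl.stop - sl.start
        a = np.repeat(ages[sl], fine.size)
        e = None if edis is None else np.repeat(edis[sl], fine.size)
        tt = np.tile(fine, nb)
        eta = fit.spec.design_matrix(tt, a, e) @ fit.beta
        lam = np.exp(eta).reshape(nb, fine.size)
        cum = cumulative_trapezoid(lam, fine, axis=1, initial=0.0)
        s_sum += np.exp(-cum).sum(axis=0)
    return np.interp(t, fine, s_sum / len(df))


def adequacy_check(fit: FittedModel, cohort, lifetable: LifeTable,
                   time_grid=None, report_times=DEFAULT_EHR_TIMES) -> AdequacyReport:
    """Compare the population-averaged model curve with Pohar-Perme."""
    df = cohort.df if hasattr(cohort, "df") else cohort
    t_max = float(df["time_years"].max())
    if time_grid is None:
        time_grid = np.linspace(0.05, min(5.0, t_max), 40)
    time_grid = np.asarray(time_grid, dtype=float)
    inside = time_grid <= t_max
    if not inside.any():
        return AdequacyReport(time_grid, np.full_like(time_grid, np.nan),
                              np.full_like(time_grid, np.nan), np.nan,
                              pd.DataFrame(), comparable=False)
    time_grid = time_grid[inside]
    model = population_averaged_net_survival(fit, cohort, time_grid)
    pp = pohar_perme(cohort, lifetable, time_grid=time_grid)
    diff = model - pp.survival
    ok = np.isfinite(diff)
    sup = float(np.nanmax(np.abs(diff[ok]))) if ok.any() else np.nan
    rows = []
    for rt in report_times:
        if rt <= t_max:
            m = population_averaged_net_survival(fit, cohort, [rt])[0]
            p = pohar_perme(cohort, lifetable, time_grid=[rt]).survival[0]
            rows.append({"time": rt, "model": m, "pohar_perme": p, "diff": m - p})
    return AdequacyReport(time_grid, model, pp.survival, sup,
                          pd.DataFrame(rows), comparable=True)


def sensitivity_rerun(cohort, stratified_lifetable: LifeTable,
                      base_lifetable: LifeTable | None = None,
                      main_result: SelectionResult | None = None,
                      age: float = REFERENCE_AGE, **select_opts):
    """Re-run selection and EHR under deprivation-stratified life tables.

    Returns a dict with the stratified selection, the main selection (either
    supplied or recomputed from ``base_lifetable``), a forced-M1 EHR whenever
    M0 was selected (so a gradient estimate is always reported), and a
    side-by-side table of EHR(mQk vs mQ1).
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    if not stratified_lifetable.has_quintiles:
        raise ValidationError("sensitivity analysis needs a stratified life table")
    if df["edi_q"].isna().any():
        raise CoverageError("records without a deprivation quintile")
    if main_result is None:
        if base_lifetable is None:
            raise ValidationError("need either main_result or base_lifetable")
        main_result = select_structure(df, base_lifetable, **select_opts)
    strat = select_structure(df, stratified_lifetable, **select_opts)

    def ehr_block(result, lifetable):
        out = {"selected": result.selected,
               "ehr": compute_ehr(result.best, age=age)}
        if result.selected == "M0":
            if "M1" in result.fits:
                forced = result.fits["M1"]
            else:
                spec = ModelSpec.from_cohort("M1", df)
                forced = optimize_laml(spec, df, lifetable)
            out["ehr_forced_m1"] = compute_ehr(forced, age=age)
        return out

    main_block = ehr_block(main_result, base_lifetable)
    strat_block = ehr_block(strat, stratified_lifetable)

    def flat(block, label):
        tab = block.get("ehr_forced_m1", block["ehr"]).rows.copy()
        tab["analysis"] = label
        tab["selected"] = block["selected"]
        tab["forced_m1"] = "ehr_forced_m1" in block
        return tab

    side_by_side = pd.concat([flat(main_block, "main"),
                              flat(strat_block, "stratified")], ignore_index=True)
    return {"main": main_block, "stratified": strat_block,
            "main_selection": main_result, "stratified_selection": strat,
            "table": side_by_side}
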