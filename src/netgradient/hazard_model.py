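"""Penalized full-likelihood excess-hazard models.

The observed mortality hazard of a patient is decomposed as

    h(t, a, EDI, z) = hE(t, a, EDI) + hP(a + t, z)

where ``hE`` is the excess mortality hazard attributable to the cancer and
``hP`` the known background hazard read from a life table.  ``log hE`` is a
sum of penalized spline terms whose structure is one of

* ``M0``   : tensor(t, a)                       -- no deprivation effect
* ``M1``   : tensor(t, a) + s(EDI)              -- time-constant EDI effect
* ``M1b``  : tensor(t, a) + s(EDI) + tint(t, EDI) -- time-dependent effect
* ``M2``   : tensor(t, a, EDI)                  -- time- and age-dependent

(a degenerate ``constant`` structure, intercept only, is kept for
diagnostics: it reduces to the exponential model).

The log-likelihood uses the background hazard as a known additive offset at
event times; the background cumulative hazard is parameter-free and dropped:

    l(b) = sum_i [ d_i log(hE_i(t_i) + hP_i) - int_0^{t_i} hE_i(u) du ]

with the integral evaluated by Gauss-Legendre quadrature per subject.
Regression coefficients maximize the penalized likelihood (Newton-Raphson
with step halving); smoothing parameters maximize the Laplace approximate
marginal likelihood (LAML).  Structures are compared by corrected AIC using
effective degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import linalg, optimize

from .errors import ConvergenceError, ValidationError
from .lifetables import LifeTable
from .splines import (
    KnotSet,
    place_knots,
    rcs_design,
    rcs_grid_means,
    rcs_penalty,
    _kron_penalty,
    _row_kron,
)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "log_excess_hazard",
    "cumulative_excess_hazard",
    "penalized_log_likelihood",
    "fit_inner",
    "laml",
    "optimize_laml",
    "corrected_aic",
]

STRUCTURES = ("M0", "M1", "M1b", "M2")
DEFAULT_KNOTS = {"time": 6, "age": 5, "edi": 5}


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Spline structure for log hE: knots, quadrature size, AIC variant."""

    structure: str
    knots_time: KnotSet
    knots_age: KnotSet
    knots_edi: KnotSet | None = None
    n_quad: int = 20
    aic_variant: str = "aicc"  # or "aic"

    def __post_init__(self):
        if self.structure not in STRUCTURES + ("constant",):
            raise ValidationError(f"unknown structure {self.structure!r}")
        if self.structure != "M0" and self.structure != "constant" \
                and self.knots_edi is None:
            raise ValidationError(f"{self.structure} requires EDI knots")
        if self.n_quad < 10 and self.structure != "constant":
            raise ValidationError("need at least 10 quadrature nodes")

    # -- marginal pieces ----------------------------------------------------
    def _aug(self, x, knots):
        """Marginal design augmented with a constant column (k columns)."""
        x = np.asarray(x, dtype=float)
        return np.column_stack([np.ones(x.shape[0]), rcs_design(x, knots)])

    def _aug_means(self, knots):
        return np.concatenate([[1.0], rcs_grid_means(knots)])

    def _aug_penalty(self, knots):
        k = knots.k
        S = np.zeros((k, k))
        S[1:, 1:] = rcs_penalty(knots)
        return S

    def _cen(self, x, knots):
        """Grid-centered marginal design (k-1 columns, each grid-mean zero)."""
        return rcs_design(np.asarray(x, dtype=float), knots) - rcs_grid_means(knots)

    # -- block layout -------------------------------------------------------
    def block_sizes(self) -> dict:
        kt, ka = self.knots_time.k, self.knots_age.k
        ke = self.knots_edi.k if self.knots_edi is not None else 0
        if self.structure == "constant":
            return {}
        if self.structure == "M2":
            return {"tensor_tae": kt * ka * ke - 1}
        sizes = {"tensor_ta": kt * ka - 1}
        if self.structure in ("M1", "M1b"):
            sizes["s_edi"] = ke - 1
        if self.structure == "M1b":
            sizes["tint_te"] = (kt - 1) * (ke - 1)
        return sizes

    @property
    def ncoef(self) -> int:
        return 1 + sum(self.block_sizes().values())

    def block_slices(self) -> dict:
        out, start = {}, 1
        for name, size in self.block_sizes().items():
            out[name] = slice(start, start + size)
            start += size
        return out

    # -- design matrix ------------------------------------------------------
    def design_matrix(self, t, a, e=None) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a = np.broadcast_to(np.asarray(a, dtype=float), t.shape)
        if e is not None:
            e = np.broadcast_to(np.asarray(e, dtype=float), t.shape)
        cols = [np.ones((t.shape[0], 1))]
        if self.structure == "constant":
            return cols[0].copy()
        if self.structure == "M2":
            margins = [self._aug(t, self.knots_time), self._aug(a, self.knots_age),
                       self._aug(e, self.knots_edi)]
            means = _row_kron([self._aug_means(k)[None, :] for k in
                               (self.knots_time, self.knots_age, self.knots_edi)])[0]
            full = _row_kron(margins)[:, 1:] - means[1:]
            cols.append(full)
            return np.concatenate(cols, axis=1)
        margins = [self._aug(t, self.knots_time), self._aug(a, self.knots_age)]
        means = _row_kron([self._aug_means(self.knots_time)[None, :],
                           self._aug_means(self.knots_age)[None, :]])[0]
        cols.append(_row_kron(margins)[:, 1:] - means[1:])
        if self.structure in ("M1", "M1b"):
            cols.append(self._cen(e, self.knots_edi))
        if self.structure == "M1b":
            cols.append(_row_kron([self._cen(t, self.knots_time),
                                   self._cen(e, self.knots_edi)]))
        return np.concatenate(cols, axis=1)

    # -- penalties ----------------------------------------------------------
    def penalty_matrices(self) -> list[np.ndarray]:
        """Full-size (p x p) embedded penalties, one per smoothing parameter.

        M0 -> 2 (time, age of the t,a tensor); M1 -> 3 (+ EDI smooth);
        M1b -> 5 (+ two directions of tint); M2 -> 3 (one per margin).
        """
        p = self.ncoef
        slices = self.block_slices()
        out = []

        def embed(S_block, sl):
            S = np.zeros((p, p))
            S[sl, sl] = S_block
            return S

        if self.structure == "constant":
            return out
        if self.structure == "M2":
            knots = (self.knots_time, self.knots_age, self.knots_edi)
            items_sizes = [k.k for k in knots]
            for which, kn in enumerate(knots):
                items = list(items_sizes)
                items[which] = self._aug_penalty(kn)
                S_full = _kron_penalty(items, which)[1:, 1:]  # drop constant col
                out.append(embed(S_full, slices["tensor_tae"]))
            return out
        knots_ta = (self.knots_time, self.knots_age)
        for which, kn in enumerate(knots_ta):
            items = [self.knots_time.k, self.knots_age.k]
            items[which] = self._aug_penalty(kn)
            S_full = _kron_penalty(items, which)[1:, 1:]
            out.append(embed(S_full, slices["tensor_ta"]))
        if self.structure in ("M1", "M1b"):
            out.append(embed(rcs_penalty(self.knots_edi), slices["s_edi"]))
        if self.structure == "M1b":
            pt, pe = self.knots_time.k - 1, self.knots_edi.k - 1
            St, Se = rcs_penalty(self.knots_time), rcs_penalty(self.knots_edi)
            out.append(embed(_kron_penalty([St, pe], 0), slices["tint_te"]))
            out.append(embed(_kron_penalty([pt, Se], 1), slices["tint_te"]))
        return out

    @classmethod
    def from_cohort(cls, structure: str, cohort, n_quad: int = 20,
                    n_knots=None, aic_variant: str = "aicc") -> "ModelSpec":
        """Knots at equally spaced percentiles among deceased patients."""
        nk = dict(DEFAULT_KNOTS)
        if n_knots:
            nk.update(n_knots)
        dead = cohort[cohort["event"] == 1]
        if len(dead) == 0:
            raise ValidationError("no events in cohort; cannot place knots")
        kt = place_knots(dead["time_years"], nk["time"], "time")
        ka = place_knots(dead["age"], nk["age"], "age")
        ke = None
        if structure in ("M1", "M1b", "M2"):
            ke = place_knots(dead["edi"], nk["edi"], "edi")
        return cls(structure, kt, ka, ke, n_quad=n_quad, aic_variant=aic_variant)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "knots_time": self.knots_time.values.tolist(),
            "knots_age": self.knots_age.values.tolist(),
            "knots_edi": None if self.knots_edi is None
            else self.knots_edi.values.tolist(),
            "n_quad": self.n_quad,
            "aic_variant": self.aic_variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            d["structure"],
            KnotSet(np.array(d["knots_time"]), "time"),
            KnotSet(np.array(d["knots_age"]), "age"),
            None if d["knots_edi"] is None else KnotSet(np.array(d["knots_edi"]), "edi"),
            n_quad=d["n_quad"], aic_variant=d.get("aic_variant", "aicc"),
        )


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _needs_edi(spec: ModelSpec) -> bool:
    return spec.structure in ("M1", "M1b", "M2")


class LikelihoodData:
    """Pre-assembled design matrices and quadrature for one cohort."""

    def __init__(self, spec: ModelSpec, cohort, lifetable: LifeTable):
        t = cohort["time_years"].to_numpy(dtype=float)
        a = cohort["age"].to_numpy(dtype=float)
        e = cohort["edi"].to_numpy(dtype=float) if _needs_edi(spec) else None
        if np.any(t <= 0):
            raise ValidationError("follow-up times must be > 0 (apply the 0.5-day rule)")
        self.spec = spec
        self.delta = cohort["event"].to_numpy(dtype=float)
        self.n = len(cohort)
        self.n_events = int(self.delta.sum())
        self.total_time = float(t.sum())
        self.X_event = spec.design_matrix(t, a, e if _needs_edi(spec) else None)

        # background hazard at each subject's exit time
        q = cohort["edi_q"].to_numpy() if lifetable.has_quintiles else None
        hp = lifetable.lookup(
            a + t, cohort["diag_year_frac"].to_numpy(dtype=float) + t,
            list(cohort["sex"]), list(cohort["region"]), q,
        )
        with np.errstate(divide="ignore"):
            self.log_hp = np.where(hp > 0, np.log(np.maximum(hp, 1e-300)), -np.inf)

        # Gauss-Legendre nodes on [0, t_i] for every subject
        Q = max(spec.n_quad, 1)
        x, w = leggauss(Q)
        tq = 0.5 * t[:, None] * (x[None, :] + 1.0)       # (n, Q)
        self.wq = (0.5 * t[:, None] * w[None, :]).ravel()
        aq = np.repeat(a, Q)
        eq = np.repeat(e, Q) if _needs_edi(spec) else None
        self.X_quad = spec.design_matrix(tq.ravel(), aq, eq)

    def loglik(self, beta, need_hess: bool = True, need_grad: bool = True):
        """Unpenalized log-likelihood with gradient and (optionally) Hessian."""
        eta_e = self.X_event @ beta
        eta_q = self.X_quad @ beta
        with np.errstate(over="ignore"):
            lam_q = np.exp(np.minimum(eta_q, 500.0))
        cum = self.wq * lam_q
        log_h = np.logaddexp(eta_e, self.log_hp)         # log(hE + hP)
        f = float(np.sum(self.delta * log_h) - cum.sum())
        if not need_grad:
            return f, None, None
        sigma = np.exp(eta_e - log_h)                    # hE / (hE + hP) in [0,1]
        g = self.X_event.T @ (self.delta * sigma) - self.X_quad.T @ cum
        if not need_hess:
            return f, g, None
        w_event = self.delta * sigma * (1.0 - sigma)     # convex offset part
        H = (self.X_event.T * w_event) @ self.X_event \
            - (self.X_quad.T * cum) @ self.X_quad
        return f, g, H


def _S_lambda(lams, S_list, p):
    S = np.zeros((p, p))
    for lam, Sj in zip(lams, S_list):
        S += lam * Sj
    return S


def penalized_log_likelihood(beta, lams, spec: ModelSpec, cohort,
                             lifetable: LifeTable):
    """Value, gradient and Hessian of the penalized log-likelihood."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != spec.ncoef:
        raise ValidationError(f"beta has {beta.shape[0]} entries, spec wants {spec.ncoef}")
    data = LikelihoodData(spec, cohort, lifetable)
    S_list = spec.penalty_matrices()
    lams = np.atleast_1d(np.asarray(lams, dtype=float))
    S = _S_lambda(lams, S_list, spec.ncoef)
    f, g, H = data.loglik(beta)
    return f - 0.5 * beta @ S @ beta, g - S @ beta, H - S


@dataclass
class InnerFit:
    beta: np.ndarray
    penalized_loglik: float
    loglik: float
    H_pen: np.ndarray        # negative penalized Hessian at beta (PD)
    H_unpen_neg: np.ndarray  # negative unpenalized Hessian at beta
    converged: bool
    iterations: int
    grad_max: float


def _solve_pd(H, g):
    """Solve H x = g for (nearly) PD H, ridging if the factorization fails."""
    ridge = 0.0
    scale = max(np.mean(np.abs(np.diag(H))), 1e-12)
    for _ in range(8):
        try:
            c, low = linalg.cho_factor(H + ridge * scale * np.eye(H.shape[0]),
                                       check_finite=False)
            return linalg.cho_solve((c, low), g, check_finite=False), ridge
        except linalg.LinAlgError:
            ridge = 1e-8 if ridge == 0.0 else ridge * 100.0
    raise ConvergenceError("penalized Hessian could not be stabilized")


def fit_inner(lams, data: LikelihoodData, S_list, beta0=None,
              tol_grad: float = 1e-6, tol_f: float = 1e-9,
              maxiter: int = 100) -> InnerFit:
    """Newton-Raphson with step halving for the penalized likelihood."""
    p = data.spec.ncoef
    lams = np.atleast_1d(np.asarray(lams, dtype=float))
    S = _S_lambda(lams, S_list, p)
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(data.n_events, 1) / data.total_time)
    else:
        beta = np.asarray(beta0, dtype=float).copy()
    f, g, H = data.loglik(beta)
    fp = f - 0.5 * beta @ S @ beta
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        gp = g - S @ beta
        Hp = S - H                       # negative penalized Hessian
        step, _ = _solve_pd(Hp, gp)
        alpha = 1.0
        for _ in range(40):
            beta_new = beta + alpha * step
            f_new, _, _ = data.loglik(beta_new, need_hess=False, need_grad=False)
            fp_new = f_new - 0.5 * beta_new @ S @ beta_new
            if np.isfinite(fp_new) and fp_new >= fp - 1e-12:
                break
            alpha *= 0.5
        else:
            break
        rel_change = abs(fp_new - fp) / (abs(fp_new) + 1.0)
        f, g, H = data.loglik(beta_new)  # Hessian only at the accepted point
        beta, fp = beta_new, fp_new
        if np.max(np.abs(g - S @ beta)) < tol_grad and rel_change < tol_f:
            converged = True
            break
    gp = g - S @ beta
    return InnerFit(beta, fp, f, S - H, -H, converged, it, float(np.max(np.abs(gp))))


def _penalty_rank(S_list, p):
    if not S_list:
        return 0
    S_sum = _S_lambda(np.ones(len(S_list)), S_list, p)
    ev = linalg.eigvalsh(S_sum)
    return int(np.sum(ev > ev.max() * 1e-9))


def log_gdet_penalty(lams, S_list, p, rank):
    """log generalized determinant of sum(lam_j S_j) over its range space."""
    if rank == 0:
        return 0.0
    ev = np.sort(linalg.eigvalsh(_S_lambda(np.asarray(lams, float), S_list, p)))
    return float(np.sum(np.log(ev[-rank:])))


def _laml_from_fit(fit: InnerFit, lams, S_list, p, rank):
    sign, logdet_Hp = np.linalg.slogdet(fit.H_pen)
    if sign <= 0:
        ev = linalg.eigvalsh(fit.H_pen)
        logdet_Hp = float(np.sum(np.log(np.maximum(ev, 1e-10))))
    Mp = p - rank
    return (fit.penalized_loglik + 0.5 * log_gdet_penalty(lams, S_list, p, rank)
            - 0.5 * logdet_Hp + 0.5 * Mp * np.log(2.0 * np.pi))


def laml(lams, spec: ModelSpec, cohort, lifetable: LifeTable, beta0=None):
    """Laplace approximate marginal likelihood at fixed smoothing parameters."""
    data = LikelihoodData(spec, cohort, lifetable)
    S_list = spec.penalty_matrices()
    fit = fit_inner(lams, data, S_list, beta0=beta0)
    return _laml_from_fit(fit, lams, S_list, spec.ncoef, _penalty_rank(S_list, spec.ncoef))


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    spec: ModelSpec
    beta: np.ndarray
    lams: np.ndarray
    cov: np.ndarray              # inverse negative penalized Hessian
    loglik: float
    penalized_loglik: float
    edf: float
    laml: float
    aic: float
    aicc: float
    n_events: int
    converged: bool
    iterations: int = 0
    grad_max: float = np.nan

    @property
    def criterion(self) -> float:
        return self.aicc if self.spec.aic_variant == "aicc" else self.aic

    def linear_predictor(self, t, a, e=None):
        X = self.spec.design_matrix(np.atleast_1d(t), a, e)
        return X @ self.beta

    def excess_hazard(self, t, a, e=None):
        return np.exp(self.linear_predictor(t, a, e))

    def cumulative_excess_hazard(self, t, a, e=None, n_nodes=None):
        return cumulative_excess_hazard(self.beta, self.spec, t, a, e,
                                        n_nodes or self.spec.n_quad)

    def to_json(self, path=None) -> str:
        payload = {
            "spec": self.spec.to_dict(),
            "beta": self.beta.tolist(),
            "lams": self.lams.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "penalized_loglik": self.penalized_loglik,
            "edf": self.edf,
            "laml": self.laml,
            "aic": self.aic,
            "aicc": self.aicc,
            "n_events": self.n_events,
            "converged": self.converged,
            "iterations": self.iterations,
        }
        s = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "FittedModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            ModelSpec.from_dict(d["spec"]), np.array(d["beta"]), np.array(d["lams"]),
            np.array(d["cov"]), d["loglik"], d["penalized_loglik"], d["edf"],
            d["laml"], d["aic"], d["aicc"], d["n_events"], d["converged"],
            d.get("iterations", 0),
        )


def corrected_aic(fit: FittedModel) -> float:
    """Small-sample corrected AIC with n = number of events."""
    edf, ll, n = fit.edf, fit.loglik, fit.n_events
    if n <= edf + 1:
        raise ValidationError(f"AICc undefined: {n} events <= EDF+1 = {edf + 1:.2f}")
    return -2.0 * ll + 2.0 * edf + 2.0 * edf * (edf + 1.0) / (n - edf - 1.0)


def optimize_laml(spec: ModelSpec, cohort, lifetable: LifeTable,
                  starts=(0.1, 10.0), outer_maxiter: int = 30,
                  lam_bounds=(1e-4, 1e8)) -> FittedModel:
    """Outer quasi-Newton maximization of LAML, inner Newton for beta.

    ``starts`` are per-penalty common starting values for the smoothing
    parameters; the best of the starts is kept.
    """
    data = LikelihoodData(spec, cohort, lifetable)
    S_list = spec.penalty_matrices()
    p = spec.ncoef
    n_pen = len(S_list)
    rank = _penalty_rank(S_list, p)

    if n_pen == 0:
        lam_hat = np.zeros(0)
        best_fit = fit_inner(lam_hat, data, S_list)
    else:
        warm = {"beta": None}
        lo, hi = np.log(lam_bounds[0]), np.log(lam_bounds[1])

        def neg_laml(rho):
            fit = fit_inner(np.exp(rho), data, S_list, beta0=warm["beta"],
                            tol_grad=1e-5, maxiter=50)
            warm["beta"] = fit.beta
            val = _laml_from_fit(fit, np.exp(rho), S_list, p, rank)
            return -val if np.isfinite(val) else 1e12

        best, best_val = None, np.inf
        failures = []
        for s in starts:
            warm["beta"] = None
            try:
                res = optimize.minimize(
                    neg_laml, np.full(n_pen, np.log(s)), method="L-BFGS-B",
                    bounds=[(lo, hi)] * n_pen,
                    options={"maxiter": outer_maxiter, "eps": 1e-3,
                             "ftol": 1e-8, "maxfun": 40 * max(outer_maxiter, 1)},
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(f"start {s}: {exc}")
                continue
            if res.fun < best_val:
                best, best_val = res, res.fun
        if best is None:
            raise ConvergenceError("LAML optimization failed: " + "; ".join(failures))
        lam_hat = np.exp(best.x)
        best_fit = fit_inner(lam_hat, data, S_list, beta0=warm["beta"])

    Hp = best_fit.H_pen
    try:
        c, low = linalg.cho_factor(Hp, check_finite=False)
        cov = linalg.cho_solve((c, low), np.eye(p), check_finite=False)
    except linalg.LinAlgError:
        cov = np.linalg.pinv(Hp)
    edf = float(np.trace(cov @ best_fit.H_unpen_neg)) if n_pen else float(p)
    edf = float(np.clip(edf, 0.0, p))
    laml_val = _laml_from_fit(best_fit, lam_hat, S_list, p, rank) if n_pen \
        else best_fit.loglik
    fit = FittedModel(
        spec=spec, beta=best_fit.beta, lams=np.asarray(lam_hat, dtype=float),
        cov=cov, loglik=best_fit.loglik,
        penalized_loglik=best_fit.penalized_loglik, edf=edf, laml=laml_val,
        aic=-2.0 * best_fit.loglik + 2.0 * edf, aicc=np.nan,
        n_events=data.n_events, converged=best_fit.converged,
        iterations=best_fit.iterations, grad_max=best_fit.grad_max,
    )
    fit.aicc = corrected_aic(fit)
    return fit


# ---------------------------------------------------------------------------
# Standalone evaluation helpers
# ---------------------------------------------------------------------------

def log_excess_hazard(beta, spec: ModelSpec, t, a, e=None):
    """Linear predictor log hE(t, a, EDI) for given coefficients."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != spec.ncoef:
        raise ValidationError(f"beta has {beta.shape[0]} entries, spec wants {spec.ncoef}")
    return spec.design_matrix(np.atleast_1d(np.asarray(t, float)), a, e) @ beta


def gauss_legendre_integral(fn, t, n_nodes=20):
    """Integral of ``fn`` over [0, t] by Gauss-Legendre (vectorized over t)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x, w = leggauss(n_nodes)
    tq = 0.5 * t[:, None] * (x[None, :] + 1.0)
    wq = 0.5 * t[:, None] * w[None, :]
    return np.sum(wq * fn(tq), axis=1)


def cumulative_excess_hazard(beta, spec: ModelSpec, t, a, e=None, n_nodes=20):
    """Gauss-Legendre integral of hE over [0, t] (vectorized over t)."""
    if n_nodes < 10:
        raise ValidationError("need at least 10 quadrature nodes")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x, w = leggauss(n_nodes)
    tq = 0.5 * t[:, None] * (x[None, :] + 1.0)
    wq = 0.5 * t[:, None] * w[None, :]
    a_rep = np.repeat(np.broadcast_to(np.asarray(a, float), t.shape), n_nodes)
    e_rep = None
    if e is not None:
        e_rep = np.repeat(np.broadcast_to(np.asarray(e, float), t.shape), n_nodes)
    eta = log_excess_hazard(beta, spec, tq.ravel(), a_rep, e_rep).reshape(tq.shape)
    vals = np.exp(eta)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite excess hazard in quadrature")
    return np.sum(wq * vals, axis=1)
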