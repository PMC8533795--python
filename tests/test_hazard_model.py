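import numpy as np
import pytest
from scipy import linalg

from netgradient.cohort import ScenarioConfig, generate_cohort
from netgradient.errors import ValidationError
from netgradient.hazard_model import (
    FittedModel,
    LikelihoodData,
    ModelSpec,
    corrected_aic,
    cumulative_excess_hazard,
    fit_inner,
    laml,
    log_excess_hazard,
    log_gdet_penalty,
    optimize_laml,
    penalized_log_likelihood,
    _penalty_rank,
)
from netgradient.splines import KnotSet

KT = KnotSet(np.array([0.02, 0.3, 1.0, 2.0, 4.0, 7.0]), "time")
KA = KnotSet(np.array([45.0, 60.0, 70.0, 80.0, 92.0]), "age")
KE = KnotSet(np.array([-8.0, -3.0, -0.5, 2.0, 10.0]), "edi")


def make_spec(structure="M1", n_quad=20):
    return ModelSpec(structure, KT, KA, KE, n_quad=n_quad)


class TestLinearPredictor:
    def test_zero_coefficients_give_unit_hazard(self):
        spec = make_spec()
        eta = log_excess_hazard(np.zeros(spec.ncoef), spec,
                                [0.5, 2.0], [60.0, 70.0], [0.0, 3.0])
        np.testing.assert_array_equal(eta, 0.0)

    def test_m1_with_linear_edi_column_is_proportional(self):
        """A coefficient on the linear EDI column shifts log hE by
        beta*(e1-e2) independently of time and age."""
        spec = make_spec("M1")
        beta = np.zeros(spec.ncoef)
        sl = spec.block_slices()["s_edi"]
        beta[sl.start] = 0.024  # linear column of s(EDI)
        for t, a in [(0.1, 50.0), (3.0, 80.0)]:
            d = (log_excess_hazard(beta, spec, [t], [a], [5.1])
                 - log_excess_hazard(beta, spec, [t], [a], [-4.2]))[0]
            assert d == pytest.approx(0.024 * 9.3, rel=1e-12)

    def test_matches_manual_design_dot_product(self):
        rng = np.random.default_rng(5)
        for structure in ("M0", "M1", "M1b", "M2"):
            spec = make_spec(structure)
            beta = rng.normal(0, 0.2, spec.ncoef)
            t = rng.uniform(0.05, 6, 100)
            a = rng.uniform(46, 90, 100)
            e = rng.uniform(-7, 9, 100)
            X = spec.design_matrix(t, a, e if structure != "M0" else None)
            np.testing.assert_allclose(
                log_excess_hazard(beta, spec, t, a, e if structure != "M0" else None),
                X @ beta, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            log_excess_hazard(np.zeros(3), make_spec(), [1.0], [70.0], [0.0])


class TestCumulativeHazard:
    def test_constant_hazard(self):
        spec = ModelSpec("constant", KT, KA)
        beta = np.array([np.log(0.2)])
        got = cumulative_excess_hazard(beta, spec, [5.0], 70.0, None)
        assert got[0] == pytest.approx(1.0, rel=1e-12)

    def test_polynomial_integrand_exact(self):
        """hE(t)=2t integrates to t^2 exactly under Gauss-Legendre."""
        from numpy.polynomial.legendre import leggauss
        x, w = leggauss(20)
        for T in (0.5, 2.0, 6.0):
            tq = 0.5 * T * (x + 1)
            assert np.sum(0.5 * T * w * 2 * tq) == pytest.approx(T**2, rel=1e-13)

    def test_log_quadratic_hazard_vs_dense_oracle(self):
        """hE = exp(a + b t + c t^2): 20-node quadrature vs a dense oracle."""
        from netgradient.hazard_model import gauss_legendre_integral
        from scipy.integrate import simpson

        fn = lambda t: np.exp(-1.5 + 0.4 * t - 0.08 * t**2)
        for T in (0.5, 2.0, 5.0):
            got = gauss_legendre_integral(fn, [T], n_nodes=20)[0]
            grid = np.linspace(0, T, 20001)
            dense = simpson(fn(grid), x=grid)
            assert got == pytest.approx(dense, rel=1e-8)

    def test_spline_hazard_vs_dense_simpson(self):
        """Piecewise-cubic log-hazard: quadrature close to a dense oracle
        (the integrand is only C^2 at the knots, so agreement is looser)."""
        from scipy.integrate import simpson

        spec = make_spec("M1")
        rng = np.random.default_rng(2)
        beta = rng.normal(0, 0.15, spec.ncoef)
        T, a, e = 4.0, 72.0, 1.5
        got = cumulative_excess_hazard(beta, spec, [T], a, e, n_nodes=20)[0]
        grid = np.linspace(0, T, 20001)
        dense = simpson(
            np.exp(log_excess_hazard(beta, spec, grid, np.full_like(grid, a),
                                     np.full_like(grid, e))), x=grid)
        assert got == pytest.approx(dense, rel=1e-5)

    def test_increasing_in_followup_time_for_fitted_model(self, m1_fit):
        t = np.linspace(0.05, 6.0, 40)
        cum = m1_fit.cumulative_excess_hazard(t, 70.0, 0.0)
        assert np.all(np.diff(cum) > 0)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_excess_hazard(np.zeros(make_spec().ncoef), make_spec(),
                                     [1.0], 70.0, 0.0, n_nodes=5)


@pytest.fixture(scope="module")
def cohort(lifetable):
    cfg = ScenarioConfig(n_subjects=200, seed=3)
    return generate_cohort(cfg, lifetable).df


class TestPenalizedLikelihood:

    def test_exponential_reduction_closed_form(self, zero_lifetable,
                                               exponential_cohort):
        """With hP=0 and a constant-hazard model the likelihood is the
        exponential one, maximized at lambda = d/T."""
        df = exponential_cohort.df
        spec = ModelSpec("constant", KT, KA)
        d, T = df.event.sum(), df.time_years.sum()
        lam_hat = d / T
        val, g, H = penalized_log_likelihood(np.array([np.log(lam_hat)]), [],
                                             spec, df, zero_lifetable)
        assert val == pytest.approx(d * np.log(lam_hat) - lam_hat * T, rel=1e-10)
        assert abs(g[0]) < 1e-6 * d

    def test_gradient_and_hessian_match_finite_differences(self, cohort,
                                                           lifetable):
        spec = ModelSpec.from_cohort("M1", cohort, n_quad=12)
        rng = np.random.default_rng(0)
        data = LikelihoodData(spec, cohort, lifetable)
        S_list = spec.penalty_matrices()
        lams = np.array([2.0, 1.0, 5.0])
        S = sum(l * Sj for l, Sj in zip(lams, S_list))

        def fgh(beta):
            f, g, H = data.loglik(beta)
            return (f - 0.5 * beta @ S @ beta, g - S @ beta, H - S)

        beta = rng.normal(0, 0.3, spec.ncoef)
        f, g, H = fgh(beta)
        eps = 1e-5
        for j in rng.choice(spec.ncoef, 8, replace=False):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += eps
            bm[j] -= eps
            fp, gp, _ = fgh(bp)
            fm, gm, _ = fgh(bm)
            assert (fp - fm) / (2 * eps) == pytest.approx(
                g[j], rel=1e-5, abs=1e-5 * np.abs(g).max())
            np.testing.assert_allclose((gp - gm) / (2 * eps), H[:, j],
                                       rtol=1e-4, atol=1e-5 * np.abs(H).max())

    def test_infinite_penalty_confines_fit_to_null_space(self, cohort, lifetable):
        spec = ModelSpec.from_cohort("M1", cohort, n_quad=12)
        data = LikelihoodData(spec, cohort, lifetable)
        S_list = spec.penalty_matrices()
        fit = fit_inner(np.full(3, 1e9), data, S_list)
        for Sj in S_list:
            assert fit.beta @ Sj @ fit.beta < 1e-6

    def test_hessian_negative_semidefinite_without_background_offset(
            self, zero_lifetable, exponential_cohort):
        """With hP = 0 the log-likelihood is globally concave in beta; the
        penalized Hessian is NSD at arbitrary coefficients.  (With hP > 0
        the event term log(hE + hP) is convex in the linear predictor, so
        global concavity is not guaranteed; Newton uses step halving.)"""
        df = exponential_cohort.df.iloc[:200]
        spec = ModelSpec.from_cohort("M0", df, n_quad=12)
        data = LikelihoodData(spec, df, zero_lifetable)
        S = sum(spec.penalty_matrices())
        rng = np.random.default_rng(8)
        for _ in range(50):
            beta = rng.normal(0, 0.3, spec.ncoef)
            _, _, H = data.loglik(beta)
            ev = linalg.eigvalsh(H - S)
            assert ev.max() <= 1e-12 * np.abs(ev).max()

    def test_penalized_hessian_positive_definite_at_optimum(self, m1_fit):
        assert np.linalg.eigvalsh(np.linalg.inv(m1_fit.cov)).min() > 0


class TestInnerFit:
    def test_two_starts_reach_same_optimum(self, proportional_cohort, lifetable):
        df = proportional_cohort.df
        spec = ModelSpec.from_cohort("M1", df, n_quad=12)
        data = LikelihoodData(spec, df, lifetable)
        S_list = spec.penalty_matrices()
        lams = np.array([1.0, 1.0, 1.0])
        f1 = fit_inner(lams, data, S_list)
        rng = np.random.default_rng(1)
        f2 = fit_inner(lams, data, S_list, beta0=rng.normal(0, 0.2, spec.ncoef))
        assert f1.converged and f2.converged
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)

    def test_starting_at_optimum_converges_immediately(self, proportional_cohort,
                                                       lifetable):
        df = proportional_cohort.df
        spec = ModelSpec.from_cohort("M1", df, n_quad=12)
        data = LikelihoodData(spec, df, lifetable)
        S_list = spec.penalty_matrices()
        lams = np.array([1.0, 1.0, 1.0])
        fit = fit_inner(lams, data, S_list)
        again = fit_inner(lams, data, S_list, beta0=fit.beta)
        assert again.iterations <= 2

    def test_heavy_penalty_m0_reproduces_exponential_mle_intercept(
            self, zero_lifetable, exponential_cohort):
        df = exponential_cohort.df
        spec = ModelSpec("constant", KT, KA)
        data = LikelihoodData(spec, df, zero_lifetable)
        fit = fit_inner(np.zeros(0), data, [])
        assert fit.beta[0] == pytest.approx(
            np.log(df.event.sum() / df.time_years.sum()), abs=1e-4)


class TestLaml:
    def test_generalized_determinant_scaling(self):
        spec = make_spec("M1")
        S_list = spec.penalty_matrices()
        p = spec.ncoef
        rank1 = _penalty_rank([S_list[2]], p)
        v1 = log_gdet_penalty([1.0], [S_list[2]], p, rank1)
        v2 = log_gdet_penalty([2.0], [S_list[2]], p, rank1)
        assert v2 - v1 == pytest.approx(rank1 * np.log(2.0), rel=1e-12)

    def test_gdet_two_algorithms_agree(self):
        """Eigendecomposition vs pivoted-factorization computation of the
        generalized log-determinant."""
        spec = make_spec("M1b")
        S_list = spec.penalty_matrices()
        p = spec.ncoef
        rank = _penalty_rank(S_list, p)
        lams = np.array([0.5, 3.0, 10.0, 0.2, 7.0])
        via_eig = log_gdet_penalty(lams, S_list, p, rank)
        # independent route: project on the range space of the total penalty
        S_sum = sum(S_list)
        w, V = np.linalg.eigh(S_sum)
        U = V[:, w > w.max() * 1e-9]
        S_lam = sum(l * Sj for l, Sj in zip(lams, S_list))
        sign, via_lu = np.linalg.slogdet(U.T @ S_lam @ U)
        assert sign > 0
        assert via_eig == pytest.approx(via_lu, rel=1e-8)

    def test_laml_prefers_large_lambda_on_null_effect_data(self, lifetable):
        """On data with no EDI effect, LAML increases toward heavy smoothing
        of the EDI term in most replicates."""
        votes = 0
        for seed in range(5):
            cfg = ScenarioConfig(n_subjects=500, seed=40 + seed, effect_kind="null")
            df = generate_cohort(cfg, lifetable).df
            spec = ModelSpec.from_cohort("M1", df, n_quad=12)
            vals = [laml([1.0, 1.0, lam_e], spec, df, lifetable)
                    for lam_e in (0.1, 1e4)]
            votes += vals[1] >= vals[0]
        assert votes >= 4

    def test_refit_at_selected_lambda_reproduces_beta(self, proportional_cohort,
                                                      lifetable):
        df = proportional_cohort.df
        spec = ModelSpec.from_cohort("M1", df, n_quad=12)
        fit = optimize_laml(spec, df, lifetable, starts=(1.0,), outer_maxiter=5)
        data = LikelihoodData(spec, df, lifetable)
        again = fit_inner(fit.lams, data, spec.penalty_matrices())
        np.testing.assert_allclose(fit.beta, again.beta, atol=1e-8)

    def test_edf_bounds(self, proportional_cohort, lifetable):
        df = proportional_cohort.df
        spec = ModelSpec.from_cohort("M0", df, n_quad=12)
        fit = optimize_laml(spec, df, lifetable, starts=(1.0,), outer_maxiter=5)
        S_list = spec.penalty_matrices()
        null_dim = spec.ncoef - _penalty_rank(S_list, spec.ncoef)
        assert null_dim <= fit.edf <= spec.ncoef

    def test_curved_truth_selects_smaller_time_lambda_than_flat_truth(
            self, lifetable):
        sel = {}
        for name, shape in [("curved", 0.55), ("flat", 1.0)]:
            cfg = ScenarioConfig(
                n_subjects=1200, seed=77, effect_kind="null",
                baseline_excess_hazard={"dist": "weibull", "shape": shape,
                                        "scale": 8.0, "log_age_slope": 0.0})
            df = generate_cohort(cfg, lifetable).df
            spec = ModelSpec.from_cohort("M0", df, n_quad=12)
            fit = optimize_laml(spec, df, lifetable, starts=(1.0,),
                                outer_maxiter=8)
            sel[name] = fit.lams[0]
        assert sel["curved"] < sel["flat"]


class TestCriteria:
    def test_aicc_arithmetic(self):
        fit = FittedModel(make_spec(), np.zeros(1), np.zeros(1), np.eye(1),
                          loglik=-100.0, penalized_loglik=-100.0, edf=5.0,
                          laml=0.0, aic=210.0, aicc=np.nan, n_events=200,
                          converged=True)
        assert corrected_aic(fit) == pytest.approx(200 + 10 + 60 / 194.0)

    def test_aicc_exceeds_plain_aic(self, proportional_cohort, lifetable):
        df = proportional_cohort.df
        spec = ModelSpec.from_cohort("M0", df, n_quad=12)
        fit = optimize_laml(spec, df, lifetable, starts=(1.0,), outer_maxiter=4)
        assert fit.aicc > fit.aic

    def test_aicc_undefined_for_tiny_event_count(self):
        fit = FittedModel(make_spec(), np.zeros(1), np.zeros(1), np.eye(1),
                          loglik=-10.0, penalized_loglik=-10.0, edf=5.0,
                          laml=0.0, aic=0.0, aicc=np.nan, n_events=6,
                          converged=True)
        with pytest.raises(ValidationError):
            corrected_aic(fit)


def test_fitted_model_json_round_trip(tmp_path, proportional_cohort, lifetable):
    df = proportional_cohort.df
    spec = ModelSpec.from_cohort("M1", df, n_quad=12)
    fit = optimize_laml(spec, df, lifetable, starts=(1.0,), outer_maxiter=4)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = FittedModel.from_json(path)
    np.testing.assert_allclose(back.beta, fit.beta)
    np.testing.assert_allclose(back.cov, fit.cov)
    t = np.linspace(0.1, 4.0, 7)
    np.testing.assert_allclose(back.excess_hazard(t, 70.0, 1.0),
                               fit.excess_hazard(t, 70.0, 1.0))
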