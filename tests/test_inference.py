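import numpy as np
import pandas as pd
import pytest

from netgradient.cohort import ScenarioConfig, generate_cohort
from netgradient.errors import ValidationError
from netgradient.hazard_model import FittedModel, ModelSpec, optimize_laml
from netgradient.inference import (
    QuintileMedians,
    adequacy_check,
    compute_ehr,
    drop_missing_edi,
    pohar_perme,
    predict_net_survival,
    select_structure,
    sensitivity_rerun,
)
from netgradient.lifetables import (
    LifeTable,
    RateRatioTable,
    build_deprivation_lifetables,
)
from netgradient.splines import KnotSet

KT = KnotSet(np.array([0.02, 0.3, 1.0, 2.0, 4.0, 7.0]), "time")
KA = KnotSet(np.array([45.0, 60.0, 70.0, 80.0, 92.0]), "age")
KE = KnotSet(np.array([-8.0, -3.0, -0.5, 2.0, 10.0]), "edi")


def constant_hazard_fit(rate=0.1486):
    spec = ModelSpec("constant", KT, KA)
    return FittedModel(spec, np.array([np.log(rate)]), np.zeros(0),
                       np.array([[1e-4]]), 0.0, 0.0, 1.0, 0.0, 0.0, 0.0,
                       100, True)


class TestQuintileMedians:
    def test_defaults_are_the_national_values(self):
        m = QuintileMedians()
        assert m[1] == -4.2 and m[5] == 5.1

    def test_non_increasing_rejected(self):
        with pytest.raises(ValidationError):
            QuintileMedians((0.0, -1.0, 1.0, 2.0, 3.0))


class TestNetSurvivalPrediction:
    def test_survival_is_one_at_time_zero(self, m1_fit):
        c = predict_net_survival(m1_fit, 70.0, 0.8, [0.0, 1.0, 5.0])
        assert c.survival[0] == 1.0
        assert c.ci_low[0] == 1.0 and c.ci_high[0] == 1.0

    def test_constant_hazard_closed_form(self):
        fit = constant_hazard_fit(0.1486)
        c = predict_net_survival(fit, 70.0, None, [5.0])
        assert c.survival[0] == pytest.approx(np.exp(-0.743), rel=1e-10)

    def test_matches_exp_of_cumulative_hazard(self, m1_fit):
        grid = np.linspace(0.02, 6.0, 50)
        c = predict_net_survival(m1_fit, 70.0, 1.2, grid)
        cum = m1_fit.cumulative_excess_hazard(grid, 70.0, 1.2)
        np.testing.assert_allclose(c.survival, np.exp(-cum), atol=1e-10)

    def test_monotone_and_in_unit_interval(self, m1_fit):
        grid = np.linspace(0.0, 6.5, 80)
        c = predict_net_survival(m1_fit, 70.0, -4.2, grid)
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert np.all((c.survival > 0) & (c.survival <= 1.0))
        assert np.all(c.ci_low <= c.survival + 1e-12)
        assert np.all(c.survival <= c.ci_high + 1e-12)

    def test_extrapolation_warns(self, m1_fit):
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_net_survival(m1_fit, 70.0, 0.0,
                                 [m1_fit.spec.knots_time.values[-1] * 1.5])


class TestEHR:
    def test_m0_fit_has_unit_ehr_everywhere(self, proportional_cohort, lifetable):
        spec = ModelSpec.from_cohort("M0", proportional_cohort.df, n_quad=12)
        fit = optimize_laml(spec, proportional_cohort.df, lifetable,
                            starts=(1.0,), outer_maxiter=3)
        tab = compute_ehr(fit).rows
        np.testing.assert_array_equal(tab.ehr, 1.0)

    def test_reference_quintile_row_exactly_one_zero_width(self, m1_fit):
        tab = compute_ehr(m1_fit).rows
        q1 = tab[tab.quintile == 1]
        assert (q1.ehr == 1.0).all() and (q1.ci_low == 1.0).all() \
            and (q1.ci_high == 1.0).all()

    def test_linear_edi_coefficient_gives_closed_form_ehr(self):
        spec = ModelSpec("M1", KT, KA, KE)
        beta = np.zeros(spec.ncoef)
        beta[spec.block_slices()["s_edi"].start] = 0.024
        fit = FittedModel(spec, beta, np.ones(3), np.eye(spec.ncoef) * 1e-6,
                          0.0, 0.0, 5.0, 0.0, 0.0, 0.0, 500, True)
        tab = compute_ehr(fit).rows
        got = tab.loc[tab.quintile == 5, "ehr"].iloc[0]
        assert got == pytest.approx(np.exp(0.024 * 9.3), rel=1e-10)

    def test_m1_ehr_constant_in_time(self, m1_fit):
        tabs = [compute_ehr(m1_fit, times=[t]).rows for t in (0.1, 1.0, 4.0)]
        for k in (2, 3, 4, 5):
            vals = [tab.loc[tab.quintile == k, "ehr"].iloc[0] for tab in tabs]
            assert np.ptp(vals) < 1e-10

    def test_time_dependent_structures_report_three_times(self, m1_fit):
        # M1 collapses to one row per quintile
        assert len(compute_ehr(m1_fit).rows) == 5

    def test_ci_contains_point_estimate(self, m1_fit):
        tab = compute_ehr(m1_fit).rows
        assert ((tab.ci_low <= tab.ehr) & (tab.ehr <= tab.ci_high)).all()


class TestPoharPerme:
    def test_equals_kaplan_meier_without_background(self, exponential_cohort,
                                                    zero_lifetable):
        from lifelines import KaplanMeierFitter

        df = exponential_cohort.df.iloc[:300]
        pp = pohar_perme(df, zero_lifetable)
        km = KaplanMeierFitter().fit(df.time_years, df.event)
        kmv = km.survival_function_at_times(pp.time).to_numpy()
        np.testing.assert_allclose(pp.survival, kmv, atol=1e-12)

    def test_three_subject_hand_oracle(self, tiny_cohort_df):
        """Weights are exact exponentials of constant per-subject rates;
        the jump factors and the closed-form population term are hand-computed."""
        rates = np.zeros((120, 30, 2, 1))
        rates[:, :, 0, 0] = 0.02
        rates[:, :, 1, 0] = 0.01
        lt = LifeTable(rates, 0, 1995, ("male", "female"), ("R1",))
        c = np.array([0.02, 0.01, 0.02])  # male, female, male

        def W(t, alive):
            return sum(np.exp(c[i] * t) for i in alive)

        s1 = W(1, [0, 1, 2]) / W(0, [0, 1, 2]) * (1 - np.exp(c[0]) / W(1, [0, 1, 2]))
        s2 = s1 * W(2, [1, 2]) / W(1, [1, 2]) * (1 - np.exp(2 * c[1]) / W(2, [1, 2]))
        s3 = s2 * W(3, [2]) / W(2, [2])
        pp = pohar_perme(tiny_cohort_df, lt)
        np.testing.assert_allclose(pp.survival, [s1, s2, s3], atol=1e-10)

    def test_large_cohort_tracks_true_net_survival(self, lifetable):
        cfg = ScenarioConfig(n_subjects=4000, seed=31, effect_kind="null")
        coh = generate_cohort(cfg, lifetable)
        grid = np.linspace(0.25, 5.0, 20)
        pp = pohar_perme(coh.df, lifetable, time_grid=grid)
        k, s = (cfg.baseline_excess_hazard[key] for key in ("shape", "scale"))
        slope = cfg.baseline_excess_hazard["log_age_slope"]
        # population-mean of the true individual net survival
        true = np.exp(-np.outer(np.exp(slope * (coh.df.age - 70.0)),
                                (grid / s) ** k)).mean(axis=0)
        assert np.max(np.abs(pp.survival - true)) < 0.03

    def test_empty_cohort_rejected(self, zero_lifetable):
        with pytest.raises(ValidationError):
            pohar_perme(pd.DataFrame(columns=["time_years", "event"]),
                        zero_lifetable)

    def test_step_interpolation_on_requested_grid(self, tiny_cohort_df):
        rates = np.zeros((120, 30, 2, 1))
        lt = LifeTable(rates, 0, 1995, ("male", "female"), ("R1",))
        pp = pohar_perme(tiny_cohort_df, lt, time_grid=[0.5, 1.0, 1.5, 2.5])
        np.testing.assert_allclose(pp.survival, [1.0, 2 / 3, 2 / 3, 1 / 3])


class TestSelection:
    def test_ties_break_toward_simpler_structure(self):
        # synthetic forcing: equal criteria -> first in canonical order wins
        fits = {}
        table_rows = []
        for s in ("M0", "M1"):
            spec = ModelSpec(s, KT, KA, KE)
            fits[s] = FittedModel(spec, np.zeros(spec.ncoef), np.ones(1),
                                  np.eye(spec.ncoef), -50.0, -50.0, 4.0, 0.0,
                                  108.0, 108.2, 300, True)
        best, best_val = None, np.inf
        for s in ("M0", "M1", "M1b", "M2"):
            if s in fits and fits[s].criterion < best_val:
                best, best_val = s, fits[s].criterion
        assert best == "M0"

    def test_selection_runs_and_reports_all_structures(self, proportional_cohort,
                                                       lifetable):
        sel = select_structure(proportional_cohort.df, lifetable,
                               structures=("M0", "M1"), n_quad=12,
                               starts=(1.0,), outer_maxiter=4)
        assert set(sel.table.structure) == {"M0", "M1"}
        assert sel.selected in ("M0", "M1")
        assert sel.table.selected.sum() == 1

    def test_too_few_events_rejected(self, proportional_cohort, lifetable):
        df = proportional_cohort.df.iloc[:40]
        with pytest.raises(ValidationError):
            select_structure(df, lifetable, min_events=50)

    def test_missing_edi_dropped_with_count(self, proportional_cohort):
        df = proportional_cohort.df.copy()
        df.loc[df.index[:7], "edi"] = np.nan
        kept, n_missing = drop_missing_edi(df)
        assert n_missing == 7 and len(kept) == len(df) - 7


class TestAdequacy:
    def test_model_fitted_to_own_data_is_adequate(self, m1_fit,
                                                  proportional_cohort, lifetable):
        rep = adequacy_check(m1_fit, proportional_cohort, lifetable)
        assert rep.comparable
        assert rep.sup_distance < 0.06
        assert {"time", "model", "pohar_perme", "diff"} <= set(rep.pointwise.columns)

    def test_rigid_model_fits_worse_than_flexible(self, lifetable):
        """A curved truth: the intercept-only model sits further from
        Pohar-Perme than the spline model on the same cohort."""
        cfg = ScenarioConfig(
            n_subjects=1200, seed=55, effect_kind="null",
            baseline_excess_hazard={"dist": "weibull", "shape": 0.55,
                                    "scale": 9.0, "log_age_slope": 0.0})
        coh = generate_cohort(cfg, lifetable)
        flexible = optimize_laml(ModelSpec.from_cohort("M0", coh.df, n_quad=12),
                                 coh.df, lifetable, starts=(1.0,), outer_maxiter=5)
        rigid_spec = ModelSpec("constant", KT, KA)
        rigid = optimize_laml(rigid_spec, coh.df, lifetable)
        d_flex = adequacy_check(flexible, coh, lifetable).sup_distance
        d_rigid = adequacy_check(rigid, coh, lifetable).sup_distance
        assert d_rigid > d_flex

    def test_no_time_overlap_flags_non_comparability(self, m1_fit,
                                                     proportional_cohort,
                                                     lifetable):
        rep = adequacy_check(m1_fit, proportional_cohort, lifetable,
                             time_grid=[50.0, 60.0])
        assert not rep.comparable


class TestSensitivity:
    def test_identity_stratified_table_reproduces_main_analysis(
            self, proportional_cohort, lifetable):
        strat = build_deprivation_lifetables(lifetable, RateRatioTable(np.ones(5)))
        out = sensitivity_rerun(proportional_cohort, strat,
                                base_lifetable=lifetable,
                                structures=("M0", "M1"), n_quad=12,
                                starts=(1.0,), outer_maxiter=4)
        main = out["main"]["ehr"].rows
        sens = out["stratified"]["ehr"].rows
        assert out["main"]["selected"] == out["stratified"]["selected"]
        np.testing.assert_allclose(sens.ehr, main.ehr, atol=1e-10)

    def test_forced_m1_report_present_when_m0_selected(self, lifetable):
        cfg = ScenarioConfig(n_subjects=700, seed=2, effect_kind="null")
        coh = generate_cohort(cfg, lifetable)
        strat = build_deprivation_lifetables(lifetable, RateRatioTable(np.ones(5)))
        out = sensitivity_rerun(coh, strat, base_lifetable=lifetable,
                                structures=("M0", "M1"), n_quad=12,
                                starts=(1.0,), outer_maxiter=4)
        for block in (out["main"], out["stratified"]):
            if block["selected"] == "M0":
                assert "ehr_forced_m1" in block

    def test_unstratified_table_rejected(self, proportional_cohort, lifetable):
        with pytest.raises(ValidationError):
            sensitivity_rerun(proportional_cohort, lifetable,
                              base_lifetable=lifetable)
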