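"""Proportional multistate lifetable: PIFs, cohort dynamics, Monte Carlo."""

import numpy as np
import pandas as pd
import pytest

from conftest import (flat_background, single_disease_table,
                      two_cohort_population, uniform_bmi_shift)
from sugarsim.lifetable import (BMIShift, CohortState, LifetableConfig,
                                MonteCarloConfig, flatten_delta, monte_carlo,
                                pif, pif_from_bmi, rr_from_bmi, run_model,
                                step_cohort)


class TestPIF:
    def test_identical_distributions_give_zero(self):
        bmi = np.array([24.0, 29.0, 33.0])
        w = np.array([1.0, 2.0, 1.0])
        assert pif_from_bmi(bmi, bmi, w, 1.1) == 0.0

    def test_flat_risk_function_gives_zero(self):
        b0 = np.array([25.0, 30.0])
        assert pif_from_bmi(b0, b0 - 2.0, np.ones(2), 1.0) == 0.0

    def test_two_person_hand_example(self):
        # weights (1,1), baseline RRs (2,1), scenario RRs (1,1):
        # PIF = (3 - 2) / 3 = 1/3
        assert pif([2.0, 1.0], [1.0, 1.0], [1.0, 1.0]) == pytest.approx(1 / 3)

    def test_matches_brute_force_on_small_distributions(self):
        """Weighted PIF equals explicit per-person summation for any
        distribution of up to 10 people."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = rng.integers(1, 11)
            bmi0 = rng.uniform(18, 42, n)
            bmi1 = bmi0 - rng.uniform(0, 2, n)
            w = rng.uniform(0.2, 3.0, n)
            rr = rng.uniform(1.01, 1.3)
            num = sum(wi * rr ** (b - 22.0) for wi, b in zip(w, bmi0)) \
                - sum(wi * rr ** (b - 22.0) for wi, b in zip(w, bmi1))
            den = sum(wi * rr ** (b - 22.0) for wi, b in zip(w, bmi0))
            assert pif_from_bmi(bmi0, bmi1, w, rr) == pytest.approx(
                num / den, abs=1e-12)

    def test_exposure_reduction_gives_positive_pif(self):
        b0 = np.array([28.0, 35.0, 24.0])
        assert pif_from_bmi(b0, b0 - 0.7, np.ones(3), 1.15) > 0

    def test_mismatched_weights_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            pif([1.0, 2.0], [1.0, 2.0], [1.0])

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            pif([], [], [])

    def test_rr_scaling_is_exponential_in_bmi(self):
        assert rr_from_bmi(23.0, 1.1) == pytest.approx(1.1)
        assert rr_from_bmi(22.0, 1.1) == pytest.approx(1.0)
        assert rr_from_bmi(27.0, 1.1) == pytest.approx(1.1**5)


class TestCohortDynamics:
    def run_steps(self, table, background, years, start_age=40, alive=1e4):
        state = CohortState(
            sex="male", start_ages=np.array([start_age]),
            alive=np.array([alive]),
            prevalence=np.zeros((1, len(table.diseases))),
            cases=np.zeros(len(table.diseases)))
        states = [state]
        for _ in range(years):
            state = step_cohort(state, table, background)
            states.append(state)
        return states

    def test_prevalence_matches_two_state_closed_form(self):
        """Single disease, constant incidence and case fatality, no
        remission: prevalence after t annual steps equals the closed-form
        solution of dC/dt = i(1-C) - f*C within 1e-6 over 50 years."""
        i, f = 0.01, 0.05
        table = single_disease_table(incidence=i, case_fatality=f)
        background = flat_background(mortality=0.005)
        states = self.run_steps(table, background, 50)
        c_star = i / (i + f)
        for t, state in enumerate(states):
            expected = c_star * (1.0 - np.exp(-(i + f) * t))
            assert state.prevalence[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_pure_background_mortality_matches_lifetable_oracle(self):
        """With zero incidence and case fatality the population declines by
        background mortality alone and person-years equal the standard
        lifetable value with mid-interval accrual."""
        m = 0.02
        table = single_disease_table(incidence=0.0, case_fatality=0.0)
        background = flat_background(mortality=m)
        n0, years = 1e4, 30
        states = self.run_steps(table, background, years, alive=n0)
        assert states[-1].alive[0] == pytest.approx(n0 * np.exp(-m * years))
        survivors = n0 * np.exp(-m * np.arange(years + 1))
        expected_py = 0.5 * (survivors[:-1] + survivors[1:]).sum()
        assert states[-1].life_years == pytest.approx(expected_py)
        assert (states[-1].cases == 0).all()

    def test_cohort_conservation_exact_at_every_step(self, disease_table,
                                                     background):
        state = CohortState(
            sex="female", start_ages=np.arange(25, 71),
            alive=np.full(46, 1234.5),
            prevalence=np.zeros((46, len(disease_table.diseases))),
            cases=np.zeros(len(disease_table.diseases)))
        initial = state.alive.sum()
        for _ in range(20):
            prev_alive = state.alive.copy()
            prev_deaths = state.deaths
            state = step_cohort(state, disease_table, background)
            step_deaths = state.deaths - prev_deaths
            assert state.alive.sum() + step_deaths == pytest.approx(
                prev_alive.sum(), rel=1e-15)
        assert state.alive.sum() + state.deaths == pytest.approx(initial, rel=1e-14)

    def test_out_of_range_prevalence_identified(self, disease_table, background):
        state = CohortState(
            sex="male", start_ages=np.array([50]), alive=np.array([100.0]),
            prevalence=np.full((1, len(disease_table.diseases)), 1.5),
            cases=np.zeros(len(disease_table.diseases)))
        with pytest.raises(ValueError, match="prevalence outside"):
            step_cohort(state, disease_table, background)


class TestRunModel:
    def test_null_intervention_all_deltas_bitwise_zero(self, disease_table,
                                                       background, population):
        shift = uniform_bmi_shift(delta=0.0)
        out = run_model(shift, disease_table, background, population,
                        LifetableConfig(horizon_years=10))
        for sex in ("male", "female"):
            assert out["delta"][sex]["qalys"] == 0.0
            assert out["delta"][sex]["costs"] == 0.0
            assert out["delta"][sex]["life_years"] == 0.0
            assert all(v == 0.0 for v in out["delta"][sex]["cases"].values())

    def test_bmi_reduction_averts_cases_of_linked_diseases(
            self, disease_table, background, population):
        out = run_model(uniform_bmi_shift(delta=0.7), disease_table,
                        background, population, LifetableConfig(horizon_years=10))
        for sex in ("male", "female"):
            assert out["delta"][sex]["qalys"] > 0
            assert out["delta"][sex]["cases"]["diabetes"] < 0
            assert out["delta"][sex]["cases"]["cardiovascular_disease"] < 0

    def test_longevity_only_diseases_rise_with_life_years(
            self, disease_table, background, population):
        """Diseases with unit RR gain incident cases when the intervention
        extends life (sign test)."""
        out = run_model(uniform_bmi_shift(delta=0.7), disease_table,
                        background, population, LifetableConfig(horizon_years=10))
        for sex in ("male", "female"):
            assert out["delta"][sex]["life_years"] > 0
            assert out["delta"][sex]["cases"]["lung_cancer"] >= 0
            assert out["delta"][sex]["cases"]["stomach_cancer"] >= 0

    def test_longer_horizon_accumulates_more_qalys(self, disease_table,
                                                   background, population):
        shift = uniform_bmi_shift(delta=0.5)
        q = {}
        for horizon in (10, 30):
            out = run_model(shift, disease_table, background, population,
                            LifetableConfig(horizon_years=horizon))
            q[horizon] = sum(out["delta"][s]["qalys"] for s in ("male", "female"))
        assert q[30] > q[10] > 0

    def test_diabetes_feedback_amplifies_cvd_prevention(self, background,
                                                        population):
        """With diabetes conferring risk on a second disease, averted
        diabetes prevalence further reduces that disease's incidence."""
        rows = []
        for sex in ("male", "female"):
            for dis, rr, rrd, inc in (("diabetes", 1.18, 1.0, 0.008),
                                      ("cvd", 1.05, 2.0, 0.004)):
                rows.append(pd.DataFrame({
                    "disease": dis, "sex": sex, "age": range(18, 111),
                    "incidence": inc, "case_fatality": 0.02,
                    "rr_per_bmi_unit": rr, "rr_diabetes": rrd,
                    "utility_decrement": 0.1, "annual_cost": 1000.0}))
        from sugarsim.lifetable import DiseaseTable

        with_fb = DiseaseTable(pd.concat(rows, ignore_index=True))
        no_fb_df = pd.concat(rows, ignore_index=True).assign(rr_diabetes=1.0)
        no_fb = DiseaseTable(no_fb_df)
        shift = uniform_bmi_shift(delta=0.8)
        cfg = LifetableConfig(horizon_years=20)
        cases_fb = run_model(shift, with_fb, flat_background(), population,
                             cfg)["delta"]["male"]["cases"]["cvd"]
        cases_nofb = run_model(shift, no_fb, flat_background(), population,
                               cfg)["delta"]["male"]["cases"]["cvd"]
        assert cases_fb < cases_nofb < 0

    def test_invalid_horizon_rejected(self, disease_table, background,
                                      population):
        with pytest.raises(ValueError, match="horizon"):
            run_model(uniform_bmi_shift(), disease_table, background,
                      population, LifetableConfig(horizon_years=0))


class TestMonteCarlo:
    def test_fixed_parameters_give_zero_width_intervals(self, disease_table,
                                                        background, population):
        shift = uniform_bmi_shift(delta=0.5)
        run_fn = lambda tbl: flatten_delta(  # noqa: E731
            run_model(shift, tbl, background, population,
                      LifetableConfig(horizon_years=5))["delta"], tbl.diseases)
        out = monte_carlo(run_fn, disease_table,
                          MonteCarloConfig(n_runs=20, seed=1, vary=()))
        np.testing.assert_array_equal(out["lo95"], out["hi95"])
        np.testing.assert_array_equal(out["mean"], out["central"])

    def test_same_seed_reproducible_centiles(self, disease_table, background,
                                             population):
        shift = uniform_bmi_shift(delta=0.5)
        run_fn = lambda tbl: flatten_delta(  # noqa: E731
            run_model(shift, tbl, background, population,
                      LifetableConfig(horizon_years=5))["delta"], tbl.diseases)
        mc = MonteCarloConfig(n_runs=30, seed=7)
        out1 = monte_carlo(run_fn, disease_table, mc)
        out2 = monte_carlo(run_fn, disease_table, mc)
        pd.testing.assert_frame_equal(out1, out2)

    def test_identity_passthrough_matches_theoretical_centiles(self):
        """An output that simply reports a sampled lognormal RR has an
        empirical 95% interval matching the distribution's theoretical
        2.5/97.5 centiles at n=2000, within Monte Carlo error."""
        table = single_disease_table(incidence=0.01, case_fatality=0.05,
                                     rr=1.2)
        table.rr_log_se = np.array([0.05])
        run_fn = lambda tbl: {"rr": float(tbl.rr_per_bmi_unit[0])}  # noqa: E731
        out = monte_carlo(run_fn, table, MonteCarloConfig(n_runs=2000, seed=3))
        lo_theory = np.exp(np.log(1.2) - 1.959964 * 0.05)
        hi_theory = np.exp(np.log(1.2) + 1.959964 * 0.05)
        assert out.loc["rr", "lo95"] == pytest.approx(lo_theory, rel=0.01)
        assert out.loc["rr", "hi95"] == pytest.approx(hi_theory, rel=0.01)

    def test_invalid_run_count_rejected(self):
        with pytest.raises(ValueError, match="n_runs"):
            MonteCarloConfig(n_runs=0)


class TestBMIShiftInput:
    def test_from_frame_roundtrip(self):
        frame = pd.DataFrame({
            "sex": ["male", "male", "female"], "age": [30, 40, 50],
            "bmi_baseline": [25.0, 30.0, 28.0],
            "bmi_scenario": [24.5, 29.5, 27.5],
            "survey_weight": [1.0, 2.0, 1.0]})
        shift = BMIShift.from_frame(frame)
        ages, b0, b1, w = shift.data["male"]
        np.testing.assert_array_equal(ages, [30, 40])
        np.testing.assert_array_equal(b1, [24.5, 29.5])
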