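"""PIFs, disease sub-lifetables and the proportional MSLT recursion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import tiny_bundles
from msltcea.energy_weight import BMIShift
from msltcea.mslt import (LifetableModel, discount, pif_numeric, pif_shift,
                          run_disease_lifetable, run_mslt)


class TestPIF:
    def test_null_shift_and_null_risk(self):
        assert pif_shift(0.0, 1.2) == 0.0
        assert pif_shift(0.4, 1.0) == 0.0
        assert pif_numeric((27.5, 5.0), 0.0, 1.2) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        assert pif_shift(0.2, 1.2) == pytest.approx(1 - 1.2 ** -0.2, rel=1e-12)
        assert pif_shift(0.2, 1.2) == pytest.approx(0.035807, abs=1e-5)

    def test_rejects_nonpositive_rr(self):
        with pytest.raises(ValueError):
            pif_shift(0.2, 0.0)
        with pytest.raises(ValueError):
            pif_numeric((27.5, 5.0), 0.2, -1.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(mean=st.floats(22, 33), sd=st.floats(2, 8),
           delta=st.floats(0.01, 1.0), rr=st.floats(1.01, 1.5))
    def test_numeric_matches_closed_form_under_loglinear_rr(self, mean, sd, delta, rr):
        # the uniform-shift closed form is exact for any BMI distribution
        # when risk is log-linear; the quadrature must agree to 1e-6
        assert abs(pif_numeric((mean, sd), delta, rr) - pif_shift(delta, rr)) < 1e-6

    def test_works_for_non_normal_distribution(self):
        dist = stats.lognorm(s=0.18, scale=27.0)
        pif = pif_numeric(dist, 0.3, 1.15)
        assert pif == pytest.approx(pif_shift(0.3, 1.15), abs=1e-6)

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            pif_numeric((27.5, 5.0), 0.2, 1.2, grid_spec=(5, 10.0))

    def test_quadrature_error_shrinks_with_refinement(self):
        exact = pif_shift(0.3, 1.3)
        err = [abs(pif_numeric((27.5, 5.0), 0.3, 1.3, grid_spec=(n, 4.0)) - exact)
               for n in (12, 24, 48)]
        assert err[1] < err[0] and err[2] < err[1]


class TestDiseaseLifetable:
    def test_null_disease_stays_empty(self):
        _, epi = tiny_bundles(incidence=0.0, case_fatality=0.0, remission=0.0)
        traj = run_disease_lifetable(epi, "ihd", "male", 60, end_age=62)
        assert (traj["prevalence"] == 0).all()

    def test_one_cycle_hand_value(self):
        _, epi = tiny_bundles(incidence=0.01, case_fatality=0.1, remission=0.0)
        traj = run_disease_lifetable(epi, "ihd", "male", 60, end_age=62)
        assert traj["prevalence"].iloc[0] == pytest.approx(1 - math.exp(-0.01),
                                                           rel=1e-12)

    def test_full_prevention_in_year_one(self):
        _, epi = tiny_bundles(incidence=0.05)
        traj = run_disease_lifetable(epi, "ihd", "male", 60, pif_year1=1.0,
                                     end_age=62)
        assert traj["prevalence"].iloc[0] == 0.0
        assert traj["prevalence"].iloc[1] > 0  # incidence resumes in year 2

    def test_unstable_rates_raise(self):
        _, epi = tiny_bundles(case_fatality=30.0, remission=30.0, incidence=0.5)
        with pytest.raises(ArithmeticError):
            run_disease_lifetable(epi, "ihd", "male", 60, end_age=62)


def _hand_mslt(pif, n_cycles=3, inc=0.01, cf=0.02, rem=0.0, dw=0.1,
               cost=1000.0, acm=0.01, yld=0.05, l0=1000.0, rate=0.05):
    """Independent spreadsheet-style evaluation of the documented recursion."""
    def arm(pif_y1, p_comp=None):
        p, l = 0.0, l0
        prev, halys, costs = [], [], []
        for t in range(n_cycles):
            q_i = 1 - math.exp(-inc * (1 - (pif_y1 if t == 0 else 0.0)))
            p = p + (1 - p) * q_i - p * ((1 - math.exp(-cf)) + (1 - math.exp(-rem)))
            mu = acm if p_comp is None else acm + (p - p_comp[t]) * cf
            y = yld if p_comp is None else yld + dw * (p - p_comp[t])
            q = 1 - math.exp(-mu)
            deaths = l * q
            halys.append((l - deaths / 2) * (1 - y))
            costs.append(cost * p * l)
            prev.append(p)
            l -= deaths
        return prev, halys, costs

    prev_c, haly_c, cost_c = arm(0.0)
    _, haly_i, cost_i = arm(pif, p_comp=prev_c)
    d = [(hi - hc) / (1 + rate) ** t for t, (hi, hc) in enumerate(zip(haly_i, haly_c))]
    dc = [(ci - cc) / (1 + rate) ** t for t, (ci, cc) in enumerate(zip(cost_i, cost_c))]
    return sum(d), sum(dc)


class TestLifetableModel:
    def test_zero_shift_gives_bit_exact_zero(self, population, diseases):
        out = run_mslt(population, diseases, None)
        assert out.halys_gained == 0.0
        assert out.healthcare_cost_difference == 0.0
        assert (out.per_cohort["halys_gained"] == 0).all()

    def test_three_cycle_hand_oracle(self):
        pop, epi = tiny_bundles()
        model = LifetableModel(pop, epi, age_range=(60, 60), max_age=62,
                               discount_rate=0.05)
        delta_bmi = 0.5
        shift = BMIShift(pd.DataFrame({
            "sex": ["male", "female"], "age": [60, 60],
            "delta_weight": [delta_bmi * 1.7**2] * 2,
            "delta_bmi": [delta_bmi] * 2}))
        out = model.run(shift)
        pif = 1 - 1.3 ** -delta_bmi
        halys, costs = _hand_mslt(pif)
        assert out.halys_gained == pytest.approx(halys, rel=1e-12)
        assert out.healthcare_cost_difference == pytest.approx(costs, rel=1e-12)

    def test_survivors_never_increase(self, population, diseases):
        model = LifetableModel(population, diseases, age_range=(30, 32))
        traj = model.trajectory_frame()
        for (_, _), g in traj.groupby(["sex", "start_age"]):
            assert (np.diff(g["alive"]) <= 1e-9).all()

    def test_halys_monotone_in_bmi_shift(self, population, diseases):
        model = LifetableModel(population, diseases)
        gains = []
        for delta in (0.1, 0.2, 0.4):
            t = population.table.query("25 <= age <= 49")
            shift = BMIShift(pd.DataFrame({
                "sex": t["sex"], "age": t["age"],
                "delta_weight": delta * t["height_m"]**2, "delta_bmi": delta}))
            gains.append(model.run(shift).halys_gained)
        assert gains[0] < gains[1] < gains[2]

    def test_horizon_truncation_reduces_gains(self, population, diseases):
        t = population.table.query("25 <= age <= 49")
        shift = BMIShift(pd.DataFrame({
            "sex": t["sex"], "age": t["age"],
            "delta_weight": 0.2 * t["height_m"]**2, "delta_bmi": 0.2}))
        full = run_mslt(population, diseases, shift)
        ten = run_mslt(population, diseases, shift, horizon_years=10)
        assert 0 < ten.halys_gained < full.halys_gained

    def test_cost_savings_negative_for_risk_reduction(self, population, diseases):
        t = population.table.query("25 <= age <= 49")
        shift = BMIShift(pd.DataFrame({
            "sex": t["sex"], "age": t["age"],
            "delta_weight": 0.2 * t["height_m"]**2, "delta_bmi": 0.2}))
        out = run_mslt(population, diseases, shift)
        assert out.halys_gained > 0
        assert out.healthcare_cost_difference < 0


class TestDiscount:
    def test_zero_rate_is_plain_sum(self):
        assert discount([1.0, 2.0, 3.0], 0.0) == 6.0

    def test_single_year_hand_value(self):
        assert discount([0.0, 100.0], 0.07) == pytest.approx(93.458, abs=1e-3)

    def test_lower_rate_dominates_and_grows_with_length(self):
        short = discount([10.0] * 10, 0.03) / discount([10.0] * 10, 0.07)
        long = discount([10.0] * 40, 0.03) / discount([10.0] * 40, 0.07)
        assert 1 < short < long

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount([1.0], -0.01)
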