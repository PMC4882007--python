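"""Unit and property tests for the two-compartment model core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ratabolic as rb
from ratabolic.model import energy_balance_residual

from conftest import random_run


HILL = rb.DrugParams(d0=13.0, dmax=37.0, ed50=10.0)


class TestDrugEffect:
    @pytest.mark.parametrize(
        "dose, t, expected",
        [
            (0.0, 5.0, 13.0),          # vehicle still gets handling stress
            (10.0, 5.0, 31.5),         # half-maximum at the ED50
            (30.0, 30.0, 0.0),         # outside the treatment window
            (30.0, 23.0, 0.0),         # window is half-open at the right
            (30.0, 0.0, 13.0 + 37.0 * 0.75),
        ],
    )
    def test_point_values(self, dose, t, expected):
        assert rb.drug_effect(dose, t, HILL) == pytest.approx(expected, abs=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            rb.drug_effect(-1.0, 5.0, HILL)

    def test_invalid_ed50_rejected(self):
        with pytest.raises(ValueError):
            rb.DrugParams(ed50=0.0)

    @given(
        d1=st.floats(0.0, 300.0),
        d2=st.floats(0.0, 300.0),
    )
    def test_monotone_and_saturating(self, d1, d2):
        lo, hi = sorted((d1, d2))
        e_lo = rb.drug_effect(lo, 5.0, HILL)
        e_hi = rb.drug_effect(hi, 5.0, HILL)
        assert e_lo <= e_hi + 1e-12
        assert e_hi < HILL.d0 + HILL.dmax


class TestEnergyExpenditure:
    def test_explicit_without_deposition_costs(self, params):
        p = params.replace(eta_fm=0.0, eta_ffm=0.0)
        e0 = (
            p.k + p.beta * (90.0 - p.i0)
            + (p.lam + p.gamma_fm) * 180.0
            + (p.lam + p.gamma_ffm) * 470.0
        )
        assert rb.energy_expenditure(180.0, 470.0, 90.0, p) == pytest.approx(e0, abs=1e-12)

    def test_fixed_point_at_energy_balance(self, params):
        # choose I solving I = E0(I); then E = I exactly (zero imbalance)
        p = params
        num = p.k - p.beta * p.i0 + (p.lam + p.gamma_fm) * 180.0 + (p.lam + p.gamma_ffm) * 470.0
        intake = num / (1.0 - p.beta)
        e = rb.energy_expenditure(180.0, 470.0, intake, p)
        assert e == pytest.approx(intake, abs=1e-9)

    def test_matches_damped_fixed_point_iteration(self):
        """Closed form resolves the implicit equation: iterate
        E <- E0 + c*(I - E) to convergence and compare."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rb.ModelParams(
                rho_fm=rng.uniform(8.5, 10), rho_ffm=rng.uniform(1.2, 2.5),
                eta_fm=rng.uniform(0, 0.3), eta_ffm=rng.uniform(0, 0.3),
                beta=rng.uniform(0, 0.4), gamma_fm=rng.uniform(0.005, 0.02),
                gamma_ffm=rng.uniform(0.05, 0.15), lam=rng.uniform(0.05, 0.12),
                k=rng.uniform(-20, 20), alpha=rng.uniform(0.5, 1.2),
                i0=rng.uniform(90, 120),
            )
            fm, ffm = rng.uniform(100, 250), rng.uniform(350, 550)
            intake, d = rng.uniform(50, 130), rng.uniform(0, 40)
            c = (p.eta_fm + p.alpha * p.eta_ffm) / (p.rho_fm + p.alpha * p.rho_ffm)
            e0 = (
                p.k + p.beta * (intake - p.i0)
                + (p.lam + p.gamma_fm) * fm + (p.lam + p.gamma_ffm) * ffm + d
            )
            e_iter = e0
            for _ in range(400):
                e_iter = e0 + c * (intake - e_iter)
            assert rb.energy_expenditure(fm, ffm, intake, p, d) == pytest.approx(
                e_iter, abs=1e-10
            )

    def test_example_worked_value(self):
        p = rb.ModelParams(
            rho_fm=9.4, rho_ffm=1.8, eta_fm=0.18, eta_ffm=0.23, beta=0.3,
            gamma_fm=0.01, gamma_ffm=0.1, lam=0.087, k=0.0, alpha=0.92, i0=75.0,
        )
        c = (0.18 + 0.92 * 0.23) / (9.4 + 0.92 * 1.8)
        e0 = 0.3 * (90 - 75) + (0.087 + 0.01) * 200 + (0.087 + 0.1) * 450
        e_iter = e0
        for _ in range(400):
            e_iter = e0 + c * (90.0 - e_iter)
        assert rb.energy_expenditure(200.0, 450.0, 90.0, p) == pytest.approx(e_iter, abs=1e-12)


class TestPartitionRhs:
    def test_zero_at_balance(self, params):
        p = params
        num = p.k - p.beta * p.i0 + (p.lam + p.gamma_fm) * 180.0 + (p.lam + p.gamma_ffm) * 470.0
        intake = num / (1.0 - p.beta)
        dfm, dffm = rb.partition_rhs(180.0, 470.0, intake, p)
        assert dfm == pytest.approx(0.0, abs=1e-9)
        assert dffm == pytest.approx(0.0, abs=1e-9)

    def test_composition_ratio_is_alpha(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            alpha = rng.uniform(0.4, 1.3)
            p = rb.ModelParams(alpha=alpha)
            dfm, dffm = rb.partition_rhs(
                rng.uniform(120, 240), rng.uniform(380, 540), rng.uniform(60, 140), p
            )
            assert dffm / dfm == pytest.approx(alpha, rel=1e-12)

    def test_known_surplus_arithmetic(self):
        """A 7.6 kcal/day surplus deposits 7.6/(9.4 + 0.92*1.8) g/day of fat."""
        # no deposition cost, no mass/intake terms: E = k exactly
        p = rb.ModelParams(
            eta_fm=0.0, eta_ffm=0.0, beta=0.0, gamma_fm=0.0, gamma_ffm=0.0,
            lam=0.0, k=100.0 - 7.6, alpha=0.92, rho_fm=9.4, rho_ffm=1.8, i0=100.0,
        )
        dfm, _ = rb.partition_rhs(200.0, 450.0, 100.0, p)
        assert dfm == pytest.approx(7.6 / (9.4 + 0.92 * 1.8), rel=1e-12)


class TestIntakeSchedule:
    def test_mapping_gap_names_missing_day(self):
        with pytest.raises(KeyError, match="day 2"):
            rb.IntakeSchedule.from_mapping({0: 100.0, 1: 100.0, 3: 100.0}, i0=100.0)

    def test_out_of_range_lookup(self):
        sched = rb.IntakeSchedule(0, np.full(5, 90.0), 90.0)
        with pytest.raises(KeyError, match="day 5"):
            sched.intake_on(5)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            rb.IntakeSchedule(0, np.array([90.0, -1.0]), 90.0)


class TestSimulate:
    def test_equilibrium_trajectory_is_flat(self, params):
        p = params
        num = p.k - p.beta * p.i0 + (p.lam + p.gamma_fm) * 180.0 + (p.lam + p.gamma_ffm) * 470.0
        intake = num / (1.0 - p.beta)
        sched = rb.IntakeSchedule.constant(intake, -3, 42, i0=p.i0)
        traj = rb.simulate(rb.BodyState(-3.0, 180.0, 470.0), sched, p, t_end=42)
        assert np.max(np.abs(traj.bw - 650.0)) < 1e-6

    def test_schedule_gap_raises_naming_day(self, params):
        sched = rb.IntakeSchedule(0, np.full(10, 100.0), 100.0)
        with pytest.raises(KeyError, match="day 10"):
            rb.simulate(rb.BodyState(0.0, 180.0, 470.0), sched, params, t_end=20)

    def test_energy_conservation_and_line_confinement(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            p, init, sched, drug, dose, traj = random_run(rng)
            res = energy_balance_residual(traj, sched, p, drug=drug, dose=dose)
            assert res < 1e-6
            line = init.ffm + p.alpha * (traj.fm - init.fm)
            assert np.max(np.abs(traj.ffm - line)) / np.max(np.abs(traj.ffm)) < 1e-6

    def test_drug_free_run_is_strict_superset_reduction(self):
        """dose 0 with no DrugParams reproduces the restriction-study model;
        a zero-effect drug parameterisation must match it exactly."""
        p = rb.ModelParams()
        sched = rb.IntakeSchedule.constant(0.9 * p.i0, -3, 22, i0=p.i0)
        init = rb.BodyState(-3.0, 180.0, 470.0)
        plain = rb.simulate(init, sched, p, t_end=22)
        null_drug = rb.DrugParams(d0=0.0, dmax=0.0, ed50=10.0)
        with_drug = rb.simulate(init, sched, p, drug=null_drug, dose=0.0, t_end=22)
        np.testing.assert_array_equal(plain.fm, with_drug.fm)
        np.testing.assert_array_equal(plain.ffm, with_drug.ffm)

    def test_fat_mass_clipped_with_warning(self, params):
        p = params
        sched = rb.IntakeSchedule.constant(0.3 * p.i0, 0, 40, i0=p.i0)
        with pytest.warns(RuntimeWarning, match="clipped"):
            traj = rb.simulate(rb.BodyState(0.0, 8.0, 470.0), sched, p, t_end=40)
        assert traj.fm.min() == 0.0

    def test_grid_hits_integer_days_exactly(self, params):
        sched = rb.IntakeSchedule.constant(params.i0, -3, 10, i0=params.i0)
        traj = rb.simulate(rb.BodyState(-3.0, 180.0, 470.0), sched, params, t_end=10)
        for day in range(-3, 11):
            assert traj.t[traj.day_index(day)] == pytest.approx(day, abs=1e-12)
        np.testing.assert_array_equal(traj.bw, traj.fm + traj.ffm)
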