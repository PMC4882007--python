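"""Tests for the calibration machinery: Kleiber translation, TLS line,
objective, lambda fit, drug-quartet annealing, and the identifiability
surface."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ratabolic as rb
from ratabolic import _fast
from ratabolic.calibrate import StudyDesign

from conftest import random_run


class TestKleiber:
    def test_identity_at_equal_mass(self):
        assert rb.kleiber_translate(0.2, 25.0, 25.0) == 0.2

    def test_sixteenfold_mass_halves_rate(self):
        assert rb.kleiber_translate(0.2, 25.0, 400.0) == pytest.approx(0.1, rel=1e-12)

    def test_mouse_to_rat_factor(self):
        """25 g mouse -> 350 g lean rat scales per-gram rates by
        (350/25)^(-1/4), consistent with a log-log slope of -1/4."""
        factor = rb.kleiber_translate(1.0, 25.0, 350.0)
        assert factor == pytest.approx((350.0 / 25.0) ** -0.25, rel=1e-12)
        slope = np.log(rb.kleiber_translate(1.0, 25.0, 350.0)) / np.log(350.0 / 25.0)
        assert slope == pytest.approx(-0.25, rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            rb.kleiber_translate(0.2, 0.0, 350.0)


def _brute_force_tls_slope(fm, ffm, lo=-1.5, hi=1.5, n=300001):
    """Independent oracle: scan the line slope densely, optimal offset in
    closed form per slope, minimising summed squared orthogonal distance."""
    xc = fm - fm.mean()
    yc = ffm - ffm.mean()
    slopes = np.tan(np.linspace(np.arctan(lo), np.arctan(hi), n))
    ss = ((yc[None, :] - slopes[:, None] * xc[None, :]) ** 2).sum(axis=1) / (1 + slopes**2)
    return slopes[np.argmin(ss)]


class TestTls:
    def test_exact_line_recovered_to_machine_precision(self):
        fm = np.array([100.0, 140.0, 180.0, 220.0, 260.0])
        line = rb.fit_alpha_tls(fm, 0.92 * fm + 357.0)
        assert line.slope == pytest.approx(0.92, abs=1e-12)
        assert line.intercept == pytest.approx(357.0, abs=1e-9)
        assert abs(line.orthogonal_ss) < 1e-9
        assert line.n == 5

    def test_exchange_symmetry_gives_unit_slope(self):
        """A point set symmetric under (x, y) exchange has TLS slope 1."""
        pts = np.array([[1.0, 2.0], [2.0, 1.0], [4.0, 7.0], [7.0, 4.0], [5.0, 5.0]])
        line = rb.fit_alpha_tls(pts[:, 0], pts[:, 1])
        assert line.slope == pytest.approx(1.0, rel=1e-12)

    def test_axis_swap_gives_reciprocal_slope(self):
        """Orthogonal regression treats both variables alike: swapping the
        axes inverts the slope (unlike ordinary least squares)."""
        rng = np.random.default_rng(9)
        fm = rng.uniform(100, 260, 40)
        ffm = 0.92 * fm + 357.0 + rng.normal(0, 6, 40)
        fwd = rb.fit_alpha_tls(fm, ffm)
        rev = rb.fit_alpha_tls(ffm, fm)
        assert fwd.slope == pytest.approx(1.0 / rev.slope, rel=1e-9)

    def test_noisy_points_match_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        fm = rng.uniform(100, 260, 20)
        ffm = 0.9 * fm + 350.0 + rng.normal(0, 8, 20)
        line = rb.fit_alpha_tls(fm, ffm)
        assert line.slope == pytest.approx(_brute_force_tls_slope(fm, ffm), abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rb.fit_alpha_tls([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="identical"):
            rb.fit_alpha_tls([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])
        with pytest.raises(ValueError, match="isotropic"):
            rb.fit_alpha_tls([1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="vertical"):
            rb.fit_alpha_tls([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestObjective:
    def test_perfect_fit_is_zero(self):
        bw = np.linspace(600, 580, 26)
        fm = np.array([180.0, 170.0, 160.0])
        assert rb.composition_objective(bw, fm, bw, fm) == 0.0

    def test_constant_residuals(self):
        """+1 g on 26 BW days and +2 g on 3 BC days give 1 + 4 = 5 g^2."""
        bw = np.full(26, 600.0)
        fm = np.full(3, 180.0)
        assert rb.composition_objective(bw + 1.0, fm + 2.0, bw, fm) == pytest.approx(5.0)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(2)
        sim_bw, obs_bw = rng.normal(600, 5, (2, 26))
        sim_fm, obs_fm = rng.normal(180, 5, (2, 3))
        expected = (
            np.sum((sim_bw - obs_bw) ** 2) / 26 + np.sum((sim_fm - obs_fm) ** 2) / 3
        )
        assert rb.composition_objective(sim_bw, sim_fm, obs_bw, obs_fm) == pytest.approx(
            expected, rel=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rb.composition_objective([1.0, 2.0], [1.0], [1.0], [1.0])

    @given(perm=st.permutations(range(4)))
    def test_additive_and_order_invariant_over_arms(self, perm):
        rng = np.random.default_rng(8)
        quads = []
        for _ in range(4):
            bw = rng.normal(600, 5, 10)
            fm = rng.normal(180, 5, 3)
            quads.append((bw, fm, bw + rng.normal(0, 2, 10), fm + rng.normal(0, 2, 3)))
        total = rb.study_objective(quads)
        assert total == pytest.approx(sum(rb.composition_objective(*q) for q in quads))
        assert rb.study_objective([quads[i] for i in perm]) == pytest.approx(total)


class TestFastPath:
    def test_day_map_matches_general_integrator(self):
        """The closed-form RK4 day-map composition equals the step-by-step
        integrator at every integer day."""
        rng = np.random.default_rng(41)
        for _ in range(10):
            p, init, sched, drug, dose, traj = random_run(rng)
            days = np.arange(-3, 42)
            d = np.array([rb.drug_effect(dose, float(day), drug) for day in days])
            fm_fast, ffm_fast, bw_fast = _fast.partition_day_values(
                p, sched.values, d, p.i0, init.fm, init.ffm
            )
            fm_gen = traj.at_days(np.arange(-3, 43), "fm")
            scale = np.max(np.abs(fm_gen))
            assert np.max(np.abs(fm_gen - fm_fast[:, 0])) / scale < 1e-9


class TestLambdaFit:
    def test_noiseless_recovery(self, noiseless_cr):
        _, _, arms = noiseless_cr
        fit = rb.fit_lambda_cr(arms, rb.ModelParams())
        assert abs(fit.params["lam"] - 0.087) < 1e-4
        assert fit.fixed == {"k": 0.0}

    def test_estimate_is_local_minimum(self, noiseless_cr):
        _, _, arms = noiseless_cr
        fit = rb.fit_lambda_cr(arms, rb.ModelParams())
        lam = fit.params["lam"]
        design = StudyDesign.from_arms(arms)
        p = rb.ModelParams()

        def obj(l):
            total = 0.0
            for j in range(len(design.labels)):
                pj = p.replace(lam=float(l), k=0.0)
                from ratabolic.calibrate import _single_arm_objective
                total += _single_arm_objective(design, j, pj)
            return total

        assert obj(lam * 1.5) > fit.objective
        assert obj(lam * 0.5) > fit.objective

    def test_reported_objective_round_trips(self, noiseless_cr):
        _, _, arms = noiseless_cr
        fit = rb.fit_lambda_cr(arms, rb.ModelParams())
        total = sum(v["bw"] + v["fm"] for v in fit.per_arm.values())
        assert fit.objective == pytest.approx(total, rel=1e-12)


class TestDrugFit:
    def test_same_seed_is_bitwise_reproducible(self, noiseless_cb1):
        _, _, arms = noiseless_cb1
        p = rb.ModelParams(lam=0.087, i0=112.0)
        kwargs = dict(seed=99, n_temps=8, iters_per_temp=20)
        a = rb.fit_drug_params(arms, p, **kwargs)
        b = rb.fit_drug_params(arms, p, **kwargs)
        assert a == b

    def test_invalid_bounds_rejected(self, noiseless_cb1):
        _, _, arms = noiseless_cb1
        bad = dict(rb.calibrate.DEFAULT_DRUG_BOUNDS, ed50=(5.0, 5.0))
        with pytest.raises(ValueError, match="bounds"):
            rb.fit_drug_params(arms, rb.ModelParams(), seed=1, bounds=bad)

    def test_reported_objective_round_trips(self, noiseless_cb1):
        _, _, arms = noiseless_cb1
        p = rb.ModelParams(lam=0.087, i0=112.0)
        fit = rb.fit_drug_params(arms, p, seed=5, n_temps=8, iters_per_temp=20)
        design = StudyDesign.from_arms(arms, window=(0.0, 23.0))
        q = (fit.params["k"], fit.params["d0"], fit.params["dmax"], fit.params["ed50"])
        assert fit.objective == pytest.approx(design.objective(p, quartet=q), rel=1e-12)


class TestLambdaKSurface:
    def test_single_node_equals_objective(self, noiseless_cr):
        _, _, arms = noiseless_cr
        surf = rb.lambda_k_surface(arms, [0.087], [0.0])
        assert surf.values.shape == (1, 1)
        fit = rb.fit_lambda_cr(arms, rb.ModelParams())
        ref = rb.lambda_k_surface(arms, [fit.params["lam"]], [0.0]).values[0, 0]
        assert ref == pytest.approx(fit.objective, rel=1e-9)

    def test_argmin_near_truth_on_noiseless_grid(self, noiseless_cr):
        _, _, arms = noiseless_cr
        lam_grid = np.linspace(0.077, 0.097, 11)
        k_grid = np.linspace(-10.0, 10.0, 11)
        surf = rb.lambda_k_surface(arms, lam_grid, k_grid)
        assert abs(surf.argmin[0] - 0.087) <= 0.002 + 1e-12
        assert abs(surf.argmin[1] - 0.0) <= 2.0 + 1e-12

    def test_low_error_valley_runs_diagonally(self, noiseless_cr):
        """Nodes near the minimum form a ridge with strongly correlated
        lambda and K coordinates — the identifiability signature."""
        _, _, arms = noiseless_cr
        lam_grid = np.linspace(0.05, 0.125, 31)
        k_grid = np.linspace(-40.0, 40.0, 31)
        surf = rb.lambda_k_surface(arms, lam_grid, k_grid)
        vmin = surf.values.min()
        span = surf.values.max() - vmin
        ii, jj = np.nonzero(surf.values <= vmin + 0.01 * span)
        assert len(ii) >= 5
        r = np.corrcoef(lam_grid[ii], k_grid[jj])[0, 1]
        assert abs(r) > 0.9

    def test_lambda_estimate_moves_monotonically_with_fixed_k(self, noiseless_cr):
        _, _, arms = noiseless_cr
        lam_grid = np.linspace(0.05, 0.13, 161)
        surf = rb.lambda_k_surface(arms, lam_grid, [-15.0, 0.0, 15.0])
        lam_hats = lam_grid[np.argmin(surf.values, axis=0)]
        assert lam_hats[0] > lam_hats[1] > lam_hats[2]
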