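"""Shared fixtures: default parameters, noiseless degenerate studies, and
an equilibrium-anchored random parameter draw used by the property and
equivalence tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ratabolic as rb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def draw_equilibrium_params(rng: np.random.Generator):
    """Random physiological parameter set with baseline intake anchored at
    the initial state's equilibrium, so moderate intake perturbations do
    not starve the fat compartment over a 45-day horizon."""
    fm0 = rng.uniform(150.0, 230.0)
    ffm0 = rng.uniform(420.0, 520.0)
    kw = dict(
        rho_fm=rng.uniform(8.5, 10.0),
        rho_ffm=rng.uniform(1.2, 2.5),
        eta_fm=rng.uniform(0.0, 0.3),
        eta_ffm=rng.uniform(0.0, 0.3),
        beta=rng.uniform(0.0, 0.4),
        gamma_fm=rng.uniform(0.005, 0.02),
        gamma_ffm=rng.uniform(0.05, 0.15),
        lam=rng.uniform(0.05, 0.12),
        k=rng.uniform(-15.0, 15.0),
        alpha=rng.uniform(0.5, 1.2),
    )
    i0 = (
        kw["k"]
        + kw["lam"] * (fm0 + ffm0)
        + kw["gamma_fm"] * fm0
        + kw["gamma_ffm"] * ffm0
    )
    p = rb.ModelParams(i0=i0, **kw)
    return p, rb.BodyState(-3.0, fm0, ffm0)


def random_run(rng, with_drug=True, n_days=45):
    """One simulated 45-day run at an equilibrium-anchored random draw."""
    p, init = draw_equilibrium_params(rng)
    values = p.i0 * rng.uniform(0.9, 1.1, n_days)
    sched = rb.IntakeSchedule(-3, values, p.i0)
    drug = rb.DrugParams(13.0, 37.0, 10.0) if with_drug else None
    dose = float(rng.choice([0.0, 10.0])) if with_drug else 0.0
    traj = rb.simulate(init, sched, p, drug=drug, dose=dose, t_end=-3 + n_days)
    return p, init, sched, drug, dose, traj


def _noiseless(cfg_factory, n_per_arm=2, **overrides):
    return cfg_factory(
        bw_noise_sd=0.0,
        fm_noise_sd=0.0,
        k_sd=0.0,
        baseline_intake_cv=0.0,
        intake_jitter_sd=0.0,
        baseline_bw_sd=0.0,
        bc_line_scatter_sd=0.0,
        n_per_arm=n_per_arm,
        **overrides,
    )


@pytest.fixture(scope="session")
def params():
    return rb.ModelParams()


@pytest.fixture(scope="session")
def noiseless_cr():
    """Degenerate (variability-free) caloric-restriction study."""
    cfg = _noiseless(rb.GeneratorConfig.cr_default)
    records, truth = rb.generate_study(cfg, seed=11)
    return records, truth, rb.aggregate_arms(records)


@pytest.fixture(scope="session")
def noiseless_cb1():
    """Degenerate (variability-free) drug-treatment study."""
    cfg = _noiseless(rb.GeneratorConfig.cb1ra_default)
    records, truth = rb.generate_study(cfg, seed=12)
    return records, truth, rb.aggregate_arms(records)


@pytest.fixture(scope="session")
def noisy_cr():
    records, truth = rb.generate_study(rb.GeneratorConfig.cr_default(), seed=21)
    return records, truth, rb.aggregate_arms(records)
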