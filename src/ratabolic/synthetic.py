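"""Synthetic rat intervention studies with known ground truth.

Two study designs are emulated, matching the layouts of the historical
experiments the models are built for:

``cr`` (caloric restriction)
    Diet-induced-obese Sprague-Dawley rats, baseline body weight
    ~ Normal(640 g, 62 g); an ad-libitum control arm plus arms restricted
    by 10/20/30/40% of each animal's measured baseline intake for 26
    days; baseline intake established over 4 pre-study days; DXA
    body-composition days -3/12/22; n = 10 per arm.

``cb1ra`` (CB1-receptor antagonist)
    Baseline body weight ~ Normal(695 g, 75 g); vehicle plus 3/10/30
    mg/kg daily oral doses for 23 days followed by a 15-day washout;
    body-composition days -3/24/42; n = 9-10 per arm.  Baseline intake
    is the day-0 measurement, matching the analysis convention for this
    design.

Each animal draws its baseline body composition from the population
FFM-FM line (``FFM = slope*FM + intercept`` with vertical scatter),
an individual baseline intake and basal-thermogenesis offset, and is
integrated forward with the two-compartment model (or a supplied
time/dose-varying partition profile).  Gaussian measurement noise is
added to body weight daily and fat mass on DXA days; intake is recorded
exactly (it is an allotment or a weighed quantity, not an assay).

The drug arms' intake suppression (dose-dependent, maximal in the first
week with partial tolerance thereafter) is a modelling choice of this
generator — in the real studies it is a measured outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import BodyState, IntakeSchedule, Trajectory, simulate
from .params import DrugParams, ModelParams
from .study import AnimalRecord

__all__ = [
    "GeneratorConfig",
    "generate_study",
    "generate_alpha_violating_study",
    "dose_dependent_partition",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Design constants and variance components of a synthetic study.

    ``arms`` holds restriction fractions (``kind="cr"``, 0 = ad libitum)
    or doses in mg/kg (``kind="cb1ra"``, 0 = vehicle).  Noise and
    between-animal variability default to plausible magnitudes for DXA
    and rodent-colony data (they are generator choices, not measured
    quantities).
    """

    kind: str = "cr"
    arms: tuple[float, ...] = (0.0, 0.10, 0.20, 0.30, 0.40)
    n_per_arm: tuple[int, ...] | int = 10
    baseline_bw_mean: float = 640.0
    baseline_bw_sd: float = 62.0
    bc_line_slope: float = 0.92
    bc_line_intercept: float = 357.0
    bc_line_scatter_sd: float = 8.0
    baseline_intake_mean: float = 107.0
    baseline_intake_cv: float = 0.05
    intake_jitter_sd: float = 0.05
    k_sd: float = 3.0
    bw_noise_sd: float = 5.0
    fm_noise_sd: float = 8.0
    params: ModelParams = field(default_factory=ModelParams)
    drug: DrugParams | None = None
    suppression_max: float = 0.30
    suppression_ed50: float = 10.0
    tolerance_day: int = 7
    tolerance_level: float = 0.5
    tolerance_tau: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cr", "cb1ra"):
            raise ValueError(f"unknown study kind {self.kind!r}")
        ns = self.n_counts
        if any(n < 1 for n in ns):
            raise ValueError("n_per_arm must be >= 1")
        for s in ("baseline_bw_sd", "bc_line_scatter_sd", "baseline_intake_cv",
                  "intake_jitter_sd", "k_sd", "bw_noise_sd", "fm_noise_sd"):
            if getattr(self, s) < 0:
                raise ValueError(f"{s} must be >= 0")
        if self.kind == "cr":
            if any(not 0.0 <= a < 1.0 for a in self.arms):
                raise ValueError("restriction fractions must lie in [0, 1)")
        else:
            if any(a < 0.0 for a in self.arms):
                raise ValueError("doses must be >= 0")
            if self.drug is None:
                raise ValueError("cb1ra generator requires DrugParams")

    @property
    def n_counts(self) -> tuple[int, ...]:
        if isinstance(self.n_per_arm, int):
            return tuple([self.n_per_arm] * len(self.arms))
        if len(self.n_per_arm) != len(self.arms):
            raise ValueError("n_per_arm tuple must match arms")
        return tuple(self.n_per_arm)

    # --- schedule anchors -------------------------------------------------
    @property
    def bc_days(self) -> tuple[int, ...]:
        return (-3, 12, 22) if self.kind == "cr" else (-3, 24, 42)

    @property
    def baseline_days(self) -> tuple[int, ...]:
        """Pre-study days on which baseline intake is established."""
        return (-15, -14, -13, -12) if self.kind == "cr" else ()

    @property
    def intervention_days(self) -> range:
        return range(0, 26) if self.kind == "cr" else range(0, 23)

    @property
    def measured_intake_days(self) -> tuple[int, ...]:
        if self.kind == "cr":
            return self.baseline_days + tuple(range(0, 26))
        return tuple(range(0, 38))

    @property
    def measured_bw_days(self) -> tuple[int, ...]:
        if self.kind == "cr":
            return (-3,) + tuple(range(0, 26))
        return (-3,) + tuple(range(0, 39)) + (42,)

    @property
    def sim_end(self) -> int:
        return 25 if self.kind == "cr" else 42

    def arm_label(self, value: float) -> str:
        if self.kind == "cr":
            return "adlib" if value == 0.0 else f"cr{int(round(value * 100))}"
        return "vehicle" if value == 0.0 else f"dose{value:g}"

    @classmethod
    def cr_default(cls, **overrides) -> "GeneratorConfig":
        return cls(**{"kind": "cr", **overrides})

    @classmethod
    def cb1ra_default(cls, **overrides) -> "GeneratorConfig":
        defaults = dict(
            kind="cb1ra",
            arms=(0.0, 3.0, 10.0, 30.0),
            n_per_arm=(9, 10, 10, 10),
            baseline_bw_mean=695.0,
            baseline_bw_sd=75.0,
            baseline_intake_mean=112.0,
            params=ModelParams(k=-16.6, i0=112.0),
            drug=DrugParams(d0=13.0, dmax=37.0, ed50=10.0, t_start=0.0, t_end=23.0),
        )
        defaults.update(overrides)
        return cls(**defaults)


def dose_dependent_partition(
    alpha0: float = 0.92,
    max_drop: float = 0.8,
    ed50: float = 10.0,
    window: tuple[float, float] = (0.0, 23.0),
) -> Callable[[float, float], float]:
    """Partition profile that shifts loss toward fat at higher doses.

    During the treatment window the slope becomes
    ``alpha0 * (1 - max_drop * dose/(dose + ed50))`` (a high dose makes
    weight change mostly fat), reverting to ``alpha0`` outside it.  Used
    to build worlds where no single constant partition slope can match
    all arms' body composition.
    """

    def profile(t: float, dose: float) -> float:
        if window[0] <= t < window[1]:
            return alpha0 * (1.0 - max_drop * dose / (dose + ed50))
        return alpha0

    return profile


def _intake_series(cfg: GeneratorConfig, arm_value: float, rng: np.random.Generator):
    """Per-animal true intake: returns (i0, day -> kcal/day over the full
    simulation horizon, measured-day map)."""
    jitter = lambda: float(np.exp(rng.normal(0.0, cfg.intake_jitter_sd))) \
        if cfg.intake_jitter_sd > 0 else 1.0
    base = cfg.baseline_intake_mean * (
        float(np.exp(rng.normal(0.0, cfg.baseline_intake_cv)))
        if cfg.baseline_intake_cv > 0 else 1.0
    )
    intake: dict[int, float] = {}
    if cfg.kind == "cr":
        baseline_meas = {d: base * jitter() for d in cfg.baseline_days}
        i0 = float(np.mean(list(baseline_meas.values())))
        for d in range(-3, 0):
            intake[d] = i0
        for d in range(0, 26):
            if arm_value == 0.0:
                intake[d] = base * jitter()
            else:
                intake[d] = (1.0 - arm_value) * i0
        measured = dict(baseline_meas)
        measured.update({d: intake[d] for d in range(0, 26)})
        return i0, intake, measured

    # cb1ra: dose-dependent transient suppression with partial tolerance
    smax = cfg.suppression_max * arm_value / (arm_value + cfg.suppression_ed50)
    for d in range(0, 38):
        val = base * jitter()
        if d < 23:
            if d < cfg.tolerance_day:
                shape = 1.0
            else:
                shape = cfg.tolerance_level + (1.0 - cfg.tolerance_level) * np.exp(
                    -(d - cfg.tolerance_day) / cfg.tolerance_tau
                )
            val *= 1.0 - smax * shape
        intake[d] = val
    i0 = intake[0]
    for d in range(-3, 0):
        intake[d] = i0
    for d in range(38, 42):
        intake[d] = intake[37]
    measured = {d: intake[d] for d in range(0, 38)}
    return i0, intake, measured


def generate_alpha_violating_study(
    cfg: GeneratorConfig,
    partition_profile: Callable[[float, float], float] | None = None,
    seed: int | None = None,
    return_trajectories: bool = False,
) -> tuple[list[AnimalRecord], dict]:
    """Generate a study, optionally with a time/dose-varying partition.

    With ``partition_profile=None`` (or a constant profile) this is the
    plain two-compartment world of :func:`generate_study`.  Returns the
    per-animal records plus a ground-truth dictionary (parameters, drug
    constants, per-animal draws, and — on request — the noise-free
    trajectories).

    Raises
    ------
    ValueError
        If the configuration drives any animal's fat mass to zero,
        naming the arm.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records: list[AnimalRecord] = []
    truth_animals: dict[str, dict] = {}
    trajectories: dict[str, Trajectory] = {}
    aid_counter = 0
    for arm_value, n in zip(cfg.arms, cfg.n_counts):
        label = cfg.arm_label(arm_value)
        dose = arm_value if cfg.kind == "cb1ra" else 0.0
        for _ in range(n):
            aid_counter += 1
            aid = f"r{aid_counter:03d}"
            bw0 = float(rng.normal(cfg.baseline_bw_mean, cfg.baseline_bw_sd))
            scatter = float(rng.normal(0.0, cfg.bc_line_scatter_sd))
            fm0 = (bw0 - cfg.bc_line_intercept - scatter) / (1.0 + cfg.bc_line_slope)
            if fm0 <= 0 or fm0 >= bw0:
                raise ValueError(f"arm {label}: drawn baseline composition invalid")
            ffm0 = bw0 - fm0
            i0, intake_true, intake_meas = _intake_series(cfg, arm_value, rng)
            dk = float(rng.normal(0.0, cfg.k_sd)) if cfg.k_sd > 0 else 0.0
            p_animal = cfg.params.replace(k=cfg.params.k + dk, i0=i0)
            sched = IntakeSchedule.from_mapping(intake_true, i0=i0)
            alpha_fn = (
                None
                if partition_profile is None
                else (lambda t, _d=dose: partition_profile(t, _d))
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                traj = simulate(
                    BodyState(-3.0, fm0, ffm0),
                    sched,
                    p_animal,
                    drug=cfg.drug if cfg.kind == "cb1ra" else None,
                    dose=dose,
                    t_end=cfg.sim_end,
                    alpha_profile=alpha_fn,
                )
            if np.any(traj.fm <= 0.0):
                raise ValueError(f"arm {label}: configuration drives fat mass to 0 g")
            bw_days = [d for d in cfg.measured_bw_days if d <= cfg.sim_end]
            bw_true = traj.at_days(bw_days, "bw")
            fm_days = [d for d in cfg.bc_days if d <= cfg.sim_end]
            fm_true = traj.at_days(fm_days, "fm")
            bw_obs = bw_true + (
                rng.normal(0.0, cfg.bw_noise_sd, len(bw_true)) if cfg.bw_noise_sd > 0 else 0.0
            )
            fm_obs = fm_true + (
                rng.normal(0.0, cfg.fm_noise_sd, len(fm_true)) if cfg.fm_noise_sd > 0 else 0.0
            )
            records.append(
                AnimalRecord(
                    animal_id=aid,
                    arm=label,
                    dose=dose,
                    bw={d: float(v) for d, v in zip(bw_days, bw_obs)},
                    intake={int(d): float(v) for d, v in intake_meas.items()},
                    fm={d: float(v) for d, v in zip(fm_days, fm_obs)},
                )
            )
            truth_animals[aid] = {
                "arm": label,
                "dose": dose,
                "k": cfg.params.k + dk,
                "i0": i0,
                "fm0": fm0,
                "ffm0": ffm0,
                "fm_true": {int(d): float(v) for d, v in zip(fm_days, fm_true)},
                "bw_true": {int(d): float(v) for d, v in zip(bw_days, bw_true)},
            }
            if return_trajectories:
                trajectories[aid] = traj
    truth = {
        "config": cfg,
        "params": cfg.params,
        "drug": cfg.drug,
        "partition_profile": partition_profile,
        "animals": truth_animals,
    }
    if return_trajectories:
        truth["trajectories"] = trajectories
    return records, truth


def generate_study(
    cfg: GeneratorConfig,
    seed: int | None = None,
    return_trajectories: bool = False,
) -> tuple[list[AnimalRecord], dict]:
    """Generate a constant-partition synthetic study (see module docs)."""
    return generate_alpha_violating_study(
        cfg, partition_profile=None, seed=seed, return_trajectories=return_trajectories
    )
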