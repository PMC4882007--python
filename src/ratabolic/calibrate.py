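"""Parameter estimation for the energy-balance models.

Covers the full calibration chain used for a pair of rat intervention
studies:

* allometric (Kleiber) translation of mass-specific metabolic rates
  between species — whole-body metabolic rate scales as mass^(3/4), so
  per-gram rates scale as mass^(-1/4);
* the constant partition slope ``alpha`` as a total-least-squares
  (orthogonal, errors-in-both-variables) line through pooled
  body-composition points;
* the fitting objective: sum of mean squared errors of body weight
  (daily) and fat mass (sparse DXA days) against arm means, summed over
  arms — fat-free mass is never compared directly since it is derived
  as ``BW - FM``;
* the physical-activity coefficient ``lambda`` by bounded scalar
  minimisation with basal thermogenesis ``K`` pinned at zero (the two
  are not jointly identifiable; see :func:`lambda_k_surface`);
* the four drug-study expenditure parameters ``(K, D0, Dmax, ED50)`` by
  seeded simulated annealing with a Nelder-Mead polish;
* the ``lambda``-``K`` error surface exposing the identifiability ridge.

All fits run on the closed-form RK4 day map (:mod:`ratabolic._fast`),
which reproduces the general integrator to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import _fast
from .alphafree import SmoothedBW
from .model import IntakeSchedule
from .params import DrugParams, ModelParams
from .study import AnimalRecord, StudyArm, impute_intake

__all__ = [
    "TlsLine",
    "FitResult",
    "ErrorSurface",
    "ConvergenceError",
    "kleiber_translate",
    "fit_alpha_tls",
    "pooled_bc_points",
    "composition_objective",
    "study_objective",
    "StudyDesign",
    "fit_lambda_cr",
    "fit_drug_params",
    "lambda_k_surface",
    "DEFAULT_DRUG_BOUNDS",
]

#: search box for the drug-study expenditure quartet
DEFAULT_DRUG_BOUNDS: dict[str, tuple[float, float]] = {
    "k": (-100.0, 100.0),     # kcal/day
    "d0": (0.0, 100.0),       # kcal/day
    "dmax": (0.0, 200.0),     # kcal/day
    "ed50": (0.5, 100.0),     # mg/kg
}


class ConvergenceError(RuntimeError):
    """Optimiser failed to converge; carries the best result so far."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


def kleiber_translate(gamma_ref: float, m_ref: float, m_target: float) -> float:
    """Translate a mass-specific metabolic rate between body sizes.

    Whole-body metabolic rate scales as mass^(3/4) (Kleiber's law), so a
    per-gram rate measured at lean mass ``m_ref`` becomes
    ``gamma_ref * (m_target / m_ref)**(-1/4)`` at lean mass ``m_target``
    (e.g. a 25 g mouse rate translated to a 350 g lean rat).
    """
    if m_ref <= 0 or m_target <= 0:
        raise ValueError("masses must be positive")
    return gamma_ref * (m_target / m_ref) ** (-0.25)


@dataclass(frozen=True)
class TlsLine:
    """Total-least-squares line ``FFM = slope * FM + intercept``.

    ``orthogonal_ss`` is the summed squared perpendicular distance (g^2)
    of the points to the line.
    """

    slope: float
    intercept: float
    orthogonal_ss: float
    n: int


def fit_alpha_tls(fm_points, ffm_points) -> TlsLine:
    """Orthogonal-regression line through body-composition points.

    The line passes through the centroid along the principal eigenvector
    of the centred second-moment matrix, which minimises the summed
    squared perpendicular distances (errors in both variables, the
    appropriate fit when FM and FFM are both measured with error).  The
    slope is the constant energy-partition estimate ``alpha``.

    Raises
    ------
    ValueError
        For fewer than 3 points, coincident points, isotropic scatter
        (direction undefined) or a vertical principal direction (slope
        undefined).
    """
    fm = np.asarray(fm_points, dtype=float)
    ffm = np.asarray(ffm_points, dtype=float)
    if fm.shape != ffm.shape or fm.ndim != 1:
        raise ValueError("fm and ffm must be equal-length 1-d arrays")
    n = len(fm)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    x = fm - fm.mean()
    y = ffm - ffm.mean()
    scatter = np.array([[x @ x, x @ y], [x @ y, y @ y]])
    evals, evecs = np.linalg.eigh(scatter)
    total = evals.sum()
    if total <= 0.0:
        raise ValueError("all points identical; line undefined")
    if (evals[1] - evals[0]) <= 1e-12 * total:
        raise ValueError("isotropic scatter; principal direction undefined")
    v = evecs[:, 1]
    if abs(v[0]) <= 1e-12 * np.linalg.norm(v):
        raise ValueError("vertical principal direction; slope undefined")
    slope = v[1] / v[0]
    intercept = ffm.mean() - slope * fm.mean()
    return TlsLine(slope=float(slope), intercept=float(intercept),
                   orthogonal_ss=float(evals[0]), n=n)


def pooled_bc_points(records: Sequence[AnimalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Pool individual-animal (FM, FFM) pairs over all BC days.

    FFM is derived per measurement as ``BW - FM`` on days where both are
    available.  This is the input to the partition-slope TLS fit.
    """
    fm_list, ffm_list = [], []
    for rec in records:
        for day, fm in sorted(rec.fm.items()):
            if day in rec.bw:
                fm_list.append(fm)
                ffm_list.append(rec.bw[day] - fm)
    return np.array(fm_list), np.array(ffm_list)


def composition_objective(sim_bw, sim_fm, obs_bw, obs_fm) -> float:
    """Single-arm fitting error (g^2): mean squared BW error plus mean
    squared FM error, ``sum (BW - BW_hat)^2 / N_BW + sum (FM - FM_hat)^2
    / N_FM``."""
    sim_bw = np.asarray(sim_bw, float)
    sim_fm = np.asarray(sim_fm, float)
    obs_bw = np.asarray(obs_bw, float)
    obs_fm = np.asarray(obs_fm, float)
    if sim_bw.shape != obs_bw.shape:
        raise ValueError(f"BW length mismatch: {sim_bw.shape} vs {obs_bw.shape}")
    if sim_fm.shape != obs_fm.shape:
        raise ValueError(f"FM length mismatch: {sim_fm.shape} vs {obs_fm.shape}")
    if sim_bw.size == 0 or sim_fm.size == 0:
        raise ValueError("empty observation arrays")
    return float(((sim_bw - obs_bw) ** 2).mean() + ((sim_fm - obs_fm) ** 2).mean())


def study_objective(arm_quads) -> float:
    """Sum of :func:`composition_objective` over arms (equal weights);
    additive over arms and invariant to their order."""
    return float(sum(composition_objective(*quad) for quad in arm_quads))


# ---------------------------------------------------------------------------
# study designs: pre-extracted arrays for repeated objective evaluation


@dataclass
class StudyDesign:
    """A study compiled for fast repeated objective evaluation.

    Built once from arm aggregates: the fitting horizon runs from the
    first to the last body-composition day; per-arm initial conditions
    come from the first BC measurement (``FM`` observed, ``FFM`` derived
    from the BW mean); intake schedules are imputed per the study rules.
    """

    t0: int
    t_end: int
    labels: list[str]
    dose: np.ndarray          # (m,)
    i0: np.ndarray            # (m,)
    fm0: np.ndarray           # (m,)
    ffm0: np.ndarray          # (m,)
    intake: np.ndarray        # (n_days, m)
    bw_idx: list[np.ndarray]  # per arm, day-boundary indices
    bw_obs: list[np.ndarray]
    fm_idx: list[np.ndarray]
    fm_obs: list[np.ndarray]
    window: tuple[float, float] | None
    steps_per_day: int = 10

    @classmethod
    def from_arms(
        cls,
        arms: Sequence[StudyArm],
        window: tuple[float, float] | None = None,
        steps_per_day: int = 10,
    ) -> "StudyDesign":
        t0s = {int(a.bc_days.min()) for a in arms}
        if len(t0s) != 1:
            raise ValueError(f"arms disagree on the first BC day: {sorted(t0s)}")
        t0 = t0s.pop()
        t_end = max(int(a.bc_days.max()) for a in arms)
        n_days = t_end - t0
        m = len(arms)
        intake = np.empty((n_days, m))
        dose = np.empty(m)
        i0 = np.empty(m)
        fm0 = np.empty(m)
        ffm0 = np.empty(m)
        bw_idx, bw_obs, fm_idx, fm_obs = [], [], [], []
        for j, arm in enumerate(arms):
            sched = impute_intake(arm, (t0, t_end))
            intake[:, j] = sched.values
            dose[j] = arm.dose
            i0[j] = arm.i0
            first_bc = int(arm.bc_days.min())
            fm0[j] = arm.fm_mean[np.argmin(arm.bc_days)]
            ffm0[j] = arm.bw_on(first_bc) - fm0[j]
            mask = (arm.bw_days >= t0) & (arm.bw_days <= t_end)
            bw_idx.append((arm.bw_days[mask] - t0).astype(int))
            bw_obs.append(arm.bw_mean[mask])
            fm_idx.append((arm.bc_days - t0).astype(int))
            fm_obs.append(arm.fm_mean)
        return cls(
            t0=t0, t_end=t_end, labels=[a.label for a in arms], dose=dose,
            i0=i0, fm0=fm0, ffm0=ffm0, intake=intake,
            bw_idx=bw_idx, bw_obs=bw_obs, fm_idx=fm_idx, fm_obs=fm_obs,
            window=window, steps_per_day=steps_per_day,
        )

    def _drug_matrix(self, quartet: tuple[float, float, float, float] | None) -> np.ndarray | float:
        if quartet is None or self.window is None:
            return 0.0
        _, d0, dmax, ed50 = quartet
        level = d0 + dmax * self.dose / (ed50 + self.dose)  # (m,)
        days = np.arange(self.t0, self.t_end)
        active = (days >= self.window[0]) & (days < self.window[1])
        return active[:, None] * level[None, :]

    def day_values(
        self, p: ModelParams, quartet=None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(FM, FFM, BW) at day boundaries, shape (n_days+1, m)."""
        if quartet is not None:
            p = p.replace(k=quartet[0])
        d = self._drug_matrix(quartet)
        return _fast.partition_day_values(
            p, self.intake, d, self.i0, self.fm0, self.ffm0, self.steps_per_day
        )

    def objective(self, p: ModelParams, quartet=None) -> float:
        total, _ = self.objective_parts(p, quartet)
        return total

    def objective_parts(
        self, p: ModelParams, quartet=None
    ) -> tuple[float, dict[str, dict[str, float]]]:
        """Total objective plus a per-arm {bw, fm} breakdown (g^2)."""
        fm, _, bw = self.day_values(p, quartet)
        per_arm: dict[str, dict[str, float]] = {}
        total = 0.0
        for j, label in enumerate(self.labels):
            bw_err = float(((bw[self.bw_idx[j], j] - self.bw_obs[j]) ** 2).mean())
            fm_err = float(((fm[self.fm_idx[j], j] - self.fm_obs[j]) ** 2).mean())
            per_arm[label] = {"bw": bw_err, "fm": fm_err}
            total += bw_err + fm_err
        return total, per_arm


class AlphaFreeStudyDesign:
    """Alpha-free analogue of :class:`StudyDesign`.

    Each arm is driven by its own body-weight input (a smoothing spline
    of the arm's mean BW, or an exact model input).  The body-weight
    part of the objective does not depend on the expenditure parameters
    (the input *is* the BW prediction), so it is precomputed; only the
    fat-mass path is re-integrated per evaluation.
    """

    def __init__(
        self,
        arms: Sequence[StudyArm],
        bw_inputs: Sequence[SmoothedBW],
        p: ModelParams,
        window: tuple[float, float] | None = None,
        steps_per_day: int = 10,
    ) -> None:
        if len(bw_inputs) != len(arms):
            raise ValueError("one body-weight input per arm required")
        base = StudyDesign.from_arms(arms, window=window, steps_per_day=steps_per_day)
        self.base = base
        self.steps_per_day = steps_per_day
        n_days = base.t_end - base.t0
        n_steps = n_days * steps_per_day
        h = 1.0 / steps_per_day
        step_t = base.t0 + np.arange(n_steps) * h
        step_day = base.t0 + (np.arange(n_steps) // steps_per_day)
        stage_t = np.stack([step_t, step_t + 0.5 * h, step_t + h], axis=1)
        stage_day = np.repeat(step_day[:, None], 3, axis=1)
        days = np.arange(base.t0, base.t_end)
        if window is not None:
            active_day = (days >= window[0]) & (days < window[1])
        else:
            active_day = np.zeros(n_days, dtype=bool)
        self._active_step = np.repeat(active_day, steps_per_day)
        self.paths: list[_fast.AlphaFreePath] = []
        self._bw_const: list[float] = []
        for j, (arm, sbw) in enumerate(zip(arms, bw_inputs)):
            s_stage = np.asarray(sbw.bw_on(stage_t, stage_day), float)
            ds_stage = np.asarray(sbw.dbw_on(stage_t, stage_day), float)
            intake_step = np.repeat(base.intake[:, j], steps_per_day)
            pj = p.replace(i0=float(base.i0[j]))
            self.paths.append(
                _fast.AlphaFreePath(
                    pj, s_stage, ds_stage, intake_step, float(base.i0[j]),
                    float(base.fm0[j]), steps_per_day,
                )
            )
            bw_pred = np.asarray(
                sbw.bw_on(base.t0 + np.asarray(base.bw_idx[j], float), None), float
            )
            self._bw_const.append(float(((bw_pred - base.bw_obs[j]) ** 2).mean()))

    def objective_parts(self, quartet) -> tuple[float, dict[str, dict[str, float]]]:
        k, d0, dmax, ed50 = quartet
        per_arm: dict[str, dict[str, float]] = {}
        total = 0.0
        for j, label in enumerate(self.base.labels):
            level = d0 + dmax * self.base.dose[j] / (ed50 + self.base.dose[j])
            d_step = np.where(self._active_step, level, 0.0)
            fm_days = self.paths[j].fm_at_days(k, d_step)
            fm_err = float(
                ((fm_days[self.base.fm_idx[j]] - self.base.fm_obs[j]) ** 2).mean()
            )
            per_arm[label] = {"bw": self._bw_const[j], "fm": fm_err}
            total += self._bw_const[j] + fm_err
        return total, per_arm

    def objective(self, quartet) -> float:
        return self.objective_parts(quartet)[0]

    def fm_day_values(self, quartet) -> np.ndarray:
        """(n_days+1, m) fat-mass day values at the given quartet."""
        k, d0, dmax, ed50 = quartet
        cols = []
        for j in range(len(self.paths)):
            level = d0 + dmax * self.base.dose[j] / (ed50 + self.base.dose[j])
            d_step = np.where(self._active_step, level, 0.0)
            cols.append(self.paths[j].fm_at_days(k, d_step))
        return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# fit results and fitting drivers


@dataclass
class FitResult:
    """Outcome of a calibration fit.

    ``objective`` always equals re-evaluating the fitting error at the
    reported estimates (asserted on construction paths in the fitters);
    ``per_arm`` breaks it down by arm and data stream.  ``trace`` holds
    optimiser metadata only (no wall-clock state), so two runs with the
    same seed produce identical results.
    """

    params: dict[str, float]
    objective: float
    fixed: dict[str, float]
    method: str
    bounds: dict[str, tuple[float, float]]
    seed: int | None
    n_eval: int
    converged: bool
    per_arm: dict[str, dict[str, float]] = field(default_factory=dict)
    trace: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "objective": self.objective,
            "fixed": self.fixed,
            "method": self.method,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed,
            "n_eval": self.n_eval,
            "converged": self.converged,
            "per_arm": self.per_arm,
            "trace": self.trace,
        }


def fit_lambda_cr(
    arms: Sequence[StudyArm],
    p: ModelParams,
    bounds: tuple[float, float] = (0.0, 0.5),
    xatol: float = 1e-10,
    max_iter: int = 200,
) -> FitResult:
    """Estimate the physical-activity coefficient ``lambda`` from a
    caloric-restriction study with basal thermogenesis pinned at K = 0.

    ``lambda`` and ``K`` trade off along a ridge of the error surface
    and cannot be identified jointly, so ``K`` is fixed and the single
    remaining expenditure parameter is found by bounded scalar
    minimisation (Brent).  All arms share one ``lambda``; each arm uses
    its own baseline intake and initial body composition.
    """
    design = StudyDesign.from_arms(arms)
    n_eval = 0

    def f(lam: float) -> float:
        nonlocal n_eval
        n_eval += 1
        total = 0.0
        for j, label in enumerate(design.labels):
            pj = p.replace(lam=float(lam), k=0.0, i0=float(design.i0[j]))
            sub = _single_arm_objective(design, j, pj)
            total += sub
        return total

    res = optimize.minimize_scalar(
        f, bounds=bounds, method="bounded", options={"xatol": xatol, "maxiter": max_iter}
    )
    lam_hat = float(res.x)
    per_arm = {}
    total = 0.0
    for j, label in enumerate(design.labels):
        pj = p.replace(lam=lam_hat, k=0.0, i0=float(design.i0[j]))
        fm, _, bw = _fast.partition_day_values(
            pj, design.intake[:, j], 0.0, design.i0[j], design.fm0[j],
            design.ffm0[j], design.steps_per_day,
        )
        bw_err = float(((bw[design.bw_idx[j], 0] - design.bw_obs[j]) ** 2).mean())
        fm_err = float(((fm[design.fm_idx[j], 0] - design.fm_obs[j]) ** 2).mean())
        per_arm[label] = {"bw": bw_err, "fm": fm_err}
        total += bw_err + fm_err
    result = FitResult(
        params={"lam": lam_hat},
        objective=total,
        fixed={"k": 0.0},
        method="brent-bounded",
        bounds={"lam": tuple(bounds)},
        seed=None,
        n_eval=n_eval,
        converged=bool(res.success),
        per_arm=per_arm,
        trace={"xatol": xatol, "scipy_message": str(res.message)},
    )
    if not res.success:
        raise ConvergenceError(
            f"lambda fit did not converge within {max_iter} iterations", best=result
        )
    return result


def _single_arm_objective(design: StudyDesign, j: int, pj: ModelParams) -> float:
    fm, _, bw = _fast.partition_day_values(
        pj, design.intake[:, j], 0.0, design.i0[j], design.fm0[j], design.ffm0[j],
        design.steps_per_day,
    )
    bw_err = ((bw[design.bw_idx[j], 0] - design.bw_obs[j]) ** 2).mean()
    fm_err = ((fm[design.fm_idx[j], 0] - design.fm_obs[j]) ** 2).mean()
    return float(bw_err + fm_err)


def _anneal(f, bounds_arr: np.ndarray, rng: np.random.Generator,
            n_temps: int, iters_per_temp: int, cooling: float,
            step_frac: float, n_probe: int = 50):
    """Generic box-bounded simulated annealing (geometric cooling,
    Gaussian proposals scaled to the box width)."""
    lo, hi = bounds_arr[:, 0], bounds_arr[:, 1]
    width = hi - lo
    dim = len(lo)
    probes = lo + rng.random((n_probe, dim)) * width
    probe_f = np.array([f(x) for x in probes])
    t0 = float(np.std(probe_f))
    if not np.isfinite(t0) or t0 == 0.0:
        t0 = 1.0
    best_i = int(np.argmin(probe_f))
    x, fx = probes[best_i].copy(), float(probe_f[best_i])
    best_x, best_f = x.copy(), fx
    n_eval = n_probe
    accepted = 0
    per_temp_best = []
    for kt in range(n_temps):
        temp = t0 * cooling**kt
        for _ in range(iters_per_temp):
            prop = np.clip(x + rng.standard_normal(dim) * step_frac * width, lo, hi)
            fp = f(prop)
            n_eval += 1
            delta = fp - fx
            if delta < 0.0 or rng.random() < np.exp(-delta / temp):
                x, fx = prop, fp
                accepted += 1
                if fx < best_f:
                    best_x, best_f = x.copy(), fx
        per_temp_best.append(best_f)
    return best_x, best_f, n_eval, accepted, t0, per_temp_best


def fit_drug_params(
    arms: Sequence[StudyArm],
    p: ModelParams,
    seed: int,
    bounds: dict[str, tuple[float, float]] | None = None,
    window: tuple[float, float] = (0.0, 23.0),
    n_temps: int = 120,
    iters_per_temp: int = 200,
    cooling: float = 0.95,
    step_frac: float = 0.05,
    model: str = "partition",
    bw_inputs: Sequence[SmoothedBW] | None = None,
    polish: bool = True,
) -> FitResult:
    """Fit the drug-study expenditure quartet ``(K, D0, Dmax, ED50)``.

    ``lambda`` is carried over from the caloric-restriction fit (fixed
    inside ``p``); the four remaining expenditure parameters are found
    by simulated annealing inside a documented box, followed by a
    Nelder-Mead polish that makes the optimum solver-independent.  The
    run is fully reproducible from ``seed``.

    Parameters
    ----------
    model : {"partition", "alpha_free"}
        Which simulator defines the objective.  ``alpha_free`` requires
        ``bw_inputs`` (one body-weight input per arm).
    """
    bounds = dict(DEFAULT_DRUG_BOUNDS if bounds is None else bounds)
    order = ("k", "d0", "dmax", "ed50")
    for name in order:
        lo, hi = bounds[name]
        if not lo < hi:
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
    bounds_arr = np.array([bounds[name] for name in order], dtype=float)

    if model == "partition":
        design = StudyDesign.from_arms(arms, window=window)
        def f(x):
            return design.objective(p, quartet=tuple(x))
    elif model == "alpha_free":
        if bw_inputs is None:
            raise ValueError("alpha_free model requires bw_inputs")
        af_design = AlphaFreeStudyDesign(arms, bw_inputs, p, window=window)
        def f(x):
            return af_design.objective(tuple(x))
    else:
        raise ValueError(f"unknown model {model!r}")

    rng = np.random.default_rng(seed)
    best_x, best_f, n_eval, accepted, t0, per_temp = _anneal(
        f, bounds_arr, rng, n_temps, iters_per_temp, cooling, step_frac
    )
    polish_nfev = 0
    if polish:
        res = optimize.minimize(
            f, best_x, method="Nelder-Mead",
            bounds=optimize.Bounds(bounds_arr[:, 0], bounds_arr[:, 1]),
            options={"xatol": 1e-8, "fatol": 1e-13, "maxiter": 4000, "maxfev": 6000},
        )
        polish_nfev = int(res.nfev)
        if res.fun <= best_f:
            best_x, best_f = np.asarray(res.x, float), float(res.fun)

    quartet = tuple(float(v) for v in best_x)
    if model == "partition":
        total, per_arm = design.objective_parts(p, quartet=quartet)
    else:
        total, per_arm = af_design.objective_parts(quartet)
    return FitResult(
        params=dict(zip(order, quartet)),
        objective=float(total),
        fixed={"lam": p.lam},
        method=f"sa+nelder-mead[{model}]",
        bounds=bounds,
        seed=seed,
        n_eval=n_eval + polish_nfev,
        converged=True,
        per_arm=per_arm,
        trace={
            "n_temps": n_temps,
            "iters_per_temp": iters_per_temp,
            "cooling": cooling,
            "step_frac": step_frac,
            "t0": t0,
            "accepted": accepted,
            "sa_best": best_f if not polish else per_temp[-1],
            "polish_nfev": polish_nfev,
        },
    )


@dataclass
class ErrorSurface:
    """Fitting error over a (lambda, K) grid.

    ``values[i, j]`` is the objective at ``lam_grid[i]``, ``k_grid[j]``;
    ``argmin`` is the grid node of the minimum.  The low-error region
    runs diagonally across the grid — the signature of the
    lambda/K identifiability ridge.
    """

    lam_grid: np.ndarray
    k_grid: np.ndarray
    values: np.ndarray
    argmin: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.lam_grid, columns=self.k_grid)
        df.index.name = "lam"
        df.columns.name = "k"
        return df


def lambda_k_surface(arms: Sequence[StudyArm], lam_grid, k_grid,
                     p: ModelParams | None = None) -> ErrorSurface:
    """Evaluate the fitting objective on a (lambda, K) grid.

    Exposes the structural non-identifiability of the two expenditure
    offsets: nodes within a few percent of the minimum form a diagonal
    valley with strongly correlated coordinates.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    k_grid = np.asarray(k_grid, dtype=float)
    if lam_grid.ndim != 1 or k_grid.ndim != 1:
        raise ValueError("grids must be 1-d")
    if np.any(np.diff(lam_grid) < 0) or np.any(np.diff(k_grid) < 0):
        raise ValueError("grids must be sorted ascending")
    if p is None:
        p = ModelParams()
    design = StudyDesign.from_arms(arms)
    values = np.empty((len(lam_grid), len(k_grid)))
    for i, lam in enumerate(lam_grid):
        for j, k in enumerate(k_grid):
            total = 0.0
            for a in range(len(design.labels)):
                pj = p.replace(lam=float(lam), k=float(k), i0=float(design.i0[a]))
                total += _single_arm_objective(design, a, pj)
            values[i, j] = total
    imin = np.unravel_index(np.argmin(values), values.shape)
    return ErrorSurface(
        lam_grid=lam_grid, k_grid=k_grid, values=values,
        argmin=(float(lam_grid[imin[0]]), float(k_grid[imin[1]])),
    )
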