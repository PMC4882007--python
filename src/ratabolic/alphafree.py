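"""Partition-free body-composition model driven by measured body weight.

The two-compartment model constrains fat and fat-free mass changes to a
fixed ratio ``alpha``.  Combining mass balance ``BW = FM + FFM`` with
energy balance ``I - E = rho_fm*dFM/dt + rho_ffm*dFFM/dt`` instead gives
a single ODE for fat mass that needs no partition assumption::

    (rho_fm - rho_ffm) * dFM/dt = I - E - rho_ffm * dBW/dt

with fat-free mass recovered as ``FFM = BW - FM``.  Body weight enters
as an *input*: a cubic smoothing spline fitted to the measured series
supplies ``BW(t)`` and its derivative.  The instantaneous composition
ratio::

    dFFM/dFM = -(I - E - rho_fm*dBW/dt) / (I - E - rho_ffm*dBW/dt)

is exposed as a diagnostic; unlike ``alpha`` it may change over time,
which is exactly what this model is designed to reveal.

The expenditure equation is again implicit in ``E`` through the
deposition terms; with ``dFFM/dt = dBW/dt - dFM/dt`` it stays linear in
``E`` and is resolved in closed form (see ``_resolve_expenditure``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from . import _fast
from .model import BodyState, IntakeSchedule, drug_effect
from .params import DrugParams, ModelParams

__all__ = [
    "SmoothedBW",
    "AlphaFreeTrajectory",
    "fit_bw_spline",
    "model_bw_input",
    "alpha_free_rhs",
    "simulate_alpha_free",
    "dffm_dfm",
]


class SmoothedBW:
    """Evaluable body-weight input: value (g) and derivative (g/day).

    Wraps a pair of vectorised callables.  ``bw_on``/``dbw_on`` accept an
    optional day-interval context which plain splines ignore; the exact
    model-generated input (:func:`model_bw_input`) uses it so that
    integration stages at day boundaries see the correct one-sided
    branch of a piecewise-defined input.
    """

    def __init__(self, bw_fn, dbw_fn, smoothing: float | None = None, knots=None):
        self._bw = bw_fn
        self._dbw = dbw_fn
        self.smoothing = smoothing
        self.knots = None if knots is None else np.asarray(knots, float)

    def bw(self, t):
        return self._bw(np.asarray(t, float))

    def dbw(self, t):
        return self._dbw(np.asarray(t, float))

    def bw_on(self, t, day=None):
        return self.bw(t)

    def dbw_on(self, t, day=None):
        return self.dbw(t)

    __call__ = bw


def fit_bw_spline(days, bw, smoothing: float = 0.2) -> SmoothedBW:
    """Cubic smoothing spline of a body-weight series.

    Uses the classical smoothing-spline objective
    ``p * sum (y - f)^2 + (1 - p) * integral f''(t)^2 dt`` with
    ``p = smoothing``: ``smoothing=0`` gives the least-squares straight
    line and ``smoothing=1`` the natural cubic interpolant.  Note that
    "smoothing factor" parameters of other spline APIs are *not*
    numerically interchangeable with this convention; when matching a
    fit from another toolbox, calibrate via effective degrees of freedom
    rather than copying the number.

    Parameters
    ----------
    days : array-like
        Observation days (>= 4 distinct values, strictly increasing after
        sorting; duplicates raise).
    bw : array-like
        Body weight (g) at those days.
    smoothing : float
        Fidelity weight ``p`` in [0, 1]; default 0.2.
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(bw, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("days and bw must be equal-length 1-d arrays")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0.0):
        dup = x[:-1][np.diff(x) == 0.0][0]
        raise ValueError(f"duplicate observation day {dup:g}")
    if len(x) < 4:
        raise ValueError(f"need at least 4 distinct days, got {len(x)}")
    if not 0.0 <= smoothing <= 1.0:
        raise ValueError(f"smoothing must lie in [0, 1], got {smoothing}")
    if smoothing == 0.0:
        slope, intercept = np.polyfit(x, y, 1)
        return SmoothedBW(
            lambda t: slope * t + intercept,
            lambda t: np.broadcast_to(slope, np.shape(t)).astype(float)
            if np.ndim(t)
            else float(slope),
            smoothing=smoothing,
            knots=x,
        )
    lam = (1.0 - smoothing) / smoothing
    spline = make_smoothing_spline(x, y, lam=lam)
    deriv = spline.derivative()
    return SmoothedBW(spline, deriv, smoothing=smoothing, knots=x)


class _ModelBW(SmoothedBW):
    """Exact body-weight input generated by the two-compartment model.

    Evaluates the model's within-day solution in closed form (the model
    is linear in its state once the day's intake is frozen), so the
    alpha-free integrator can be driven by a 2-D trajectory without any
    interpolation error.  Day context selects the branch at boundaries.
    """

    def __init__(self, p: ModelParams, start_day: int, a: float, b: np.ndarray,
                 fm_days: np.ndarray, fm0: float, ffm0: float):
        self.p = p
        self.start_day = int(start_day)
        self.a = a
        self.b = np.asarray(b, float).ravel()
        self.fm_days = np.asarray(fm_days, float).ravel()
        self.fm0 = fm0
        self.ffm0 = ffm0
        self.smoothing = None
        self.knots = None

    def _fm_dfm(self, t, day=None):
        t = np.asarray(t, float)
        if day is None:
            day = np.floor(t)
        day = np.clip(np.asarray(day, float), self.start_day,
                      self.start_day + len(self.b) - 1)
        idx = (day - self.start_day).astype(int)
        tau = t - day
        bk = self.b[idx]
        fmk = self.fm_days[idx]
        if abs(self.a) < 1e-13:
            fm = fmk + bk * tau
            dfm = bk + 0.0 * tau
        else:
            xstar = -bk / self.a
            fm = xstar + (fmk - xstar) * np.exp(self.a * tau)
            dfm = self.a * fm + bk
        return fm, dfm

    def bw_on(self, t, day=None):
        fm, _ = self._fm_dfm(t, day)
        line_const = self.ffm0 - self.p.alpha * self.fm0
        out = (1.0 + self.p.alpha) * fm + line_const
        return float(out) if np.ndim(out) == 0 else out

    def dbw_on(self, t, day=None):
        _, dfm = self._fm_dfm(t, day)
        out = (1.0 + self.p.alpha) * dfm
        return float(out) if np.ndim(out) == 0 else out

    def bw(self, t):
        return self.bw_on(t)

    def dbw(self, t):
        return self.dbw_on(t)


def model_bw_input(
    init: BodyState,
    sched: IntakeSchedule,
    p: ModelParams,
    drug: DrugParams | None = None,
    dose: float = 0.0,
    t_end: int | None = None,
    steps_per_day: int = 10,
) -> SmoothedBW:
    """Body-weight input equal to a two-compartment model trajectory.

    The returned object evaluates BW(t) and dBW/dt of the model run
    exactly (closed form within each day), which makes it the reference
    input for checking that the alpha-free model reproduces the 2-D
    model when both share parameters.
    """
    t0 = int(round(init.t))
    if t_end is None:
        t_end = sched.end_day
    t_end = int(round(t_end))
    days = np.arange(t0, t_end)
    intake = sched.slice_values(t0, t_end)
    if drug is not None:
        d = np.array([drug_effect(dose, float(day), drug) for day in days])
    else:
        d = np.zeros_like(intake)
    a, b = _fast.partition_day_coeffs(p, intake, d, p.i0, init.fm, init.ffm)
    fm_days, _, _ = _fast.partition_day_values(
        p, intake, d, p.i0, init.fm, init.ffm, steps_per_day
    )
    return _ModelBW(p, t0, a, b, fm_days[:, 0], init.fm, init.ffm)


def _resolve_expenditure(fm, intake, s, ds, p: ModelParams, drug=0.0):
    """Closed-form E of the alpha-free model.

    With ``dFFM/dt = dBW/dt - dFM/dt`` substituted, E is linear:
    ``E = (E0 + eta_ffm*dBW/dt + c'*(I - rho_ffm*dBW/dt)) / (1 + c')``
    where ``c' = (eta_fm - eta_ffm)/(rho_fm - rho_ffm)``.
    """
    r = p.rho_fm - p.rho_ffm
    cp = (p.eta_fm - p.eta_ffm) / r
    if 1.0 + cp == 0.0:
        raise ZeroDivisionError("1 + c' = 0; expenditure undefined")
    e0 = (
        p.k
        + p.beta * (np.asarray(intake, float) - p.i0)
        + (p.lam + p.gamma_fm) * np.asarray(fm, float)
        + (p.lam + p.gamma_ffm) * (np.asarray(s, float) - np.asarray(fm, float))
        + drug
    )
    return (e0 + p.eta_ffm * np.asarray(ds, float) + cp * (np.asarray(intake, float) - p.rho_ffm * np.asarray(ds, float))) / (1.0 + cp)


def alpha_free_rhs(
    fm: float,
    t: float,
    sbw: SmoothedBW,
    sched: IntakeSchedule,
    p: ModelParams,
    drug: float = 0.0,
) -> float:
    """dFM/dt (g/day) of the alpha-free model at state ``fm``, time ``t``.

    ``drug`` is the already-evaluated drug effect (kcal/day).  Raises if
    ``rho_fm == rho_ffm`` (the equation degenerates).
    """
    if p.rho_fm == p.rho_ffm:
        raise ZeroDivisionError("rho_fm == rho_ffm: alpha-free model degenerate")
    day = int(np.floor(t))
    intake = sched.intake_on(day)
    s = sbw.bw_on(t, day)
    ds = sbw.dbw_on(t, day)
    e = _resolve_expenditure(fm, intake, s, ds, p, drug)
    return float((intake - e - p.rho_ffm * ds) / (p.rho_fm - p.rho_ffm))


def dffm_dfm(
    fm: float,
    t: float,
    sbw: SmoothedBW,
    sched: IntakeSchedule,
    p: ModelParams,
    drug: float = 0.0,
    denom_tol: float = 1e-8,
) -> float:
    """Instantaneous composition ratio dFFM/dFM of the alpha-free model.

    Returns ``-(I - E - rho_fm*dBW/dt) / (I - E - rho_ffm*dBW/dt)``; at a
    stationary point of fat mass (denominator within ``denom_tol``) the
    ratio is undefined and NaN is returned rather than raising.
    """
    day = int(np.floor(t))
    intake = sched.intake_on(day)
    s = sbw.bw_on(t, day)
    ds = sbw.dbw_on(t, day)
    e = _resolve_expenditure(fm, intake, s, ds, p, drug)
    num = intake - e - p.rho_fm * ds
    den = intake - e - p.rho_ffm * ds
    if abs(den) < denom_tol:
        return float("nan")
    return float(-num / den)


@dataclass
class AlphaFreeTrajectory:
    """Alpha-free simulation output on a uniform sub-daily grid.

    ``fm + ffm`` equals the body-weight input at every grid point by
    construction.  ``dffm_dfm`` is NaN where fat mass is stationary.
    """

    t: np.ndarray
    fm: np.ndarray
    ffm: np.ndarray
    bw: np.ndarray
    ee: np.ndarray
    dffm_dfm: np.ndarray
    steps_per_day: int
    start_day: int

    def day_index(self, day: float) -> int:
        idx = int(round((day - self.start_day) * self.steps_per_day))
        if idx < 0 or idx >= len(self.t):
            raise IndexError(f"day {day} outside simulated horizon")
        return idx

    def at_days(self, days, series: str = "fm") -> np.ndarray:
        arr = getattr(self, series)
        return np.array([arr[self.day_index(d)] for d in np.atleast_1d(days)])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: time, fm, ffm, bw, ee, dffm_dfm."""
        return pd.DataFrame(
            {
                "time": self.t,
                "fm": self.fm,
                "ffm": self.ffm,
                "bw": self.bw,
                "ee": self.ee,
                "dffm_dfm": self.dffm_dfm,
            }
        )


def simulate_alpha_free(
    init_fm: float,
    sbw: SmoothedBW,
    sched: IntakeSchedule,
    p: ModelParams,
    drug: DrugParams | None = None,
    dose: float = 0.0,
    t_start: int | None = None,
    t_end: int | None = None,
    steps_per_day: int = 10,
) -> AlphaFreeTrajectory:
    """Integrate the alpha-free fat-mass ODE against a body-weight input.

    Same fixed-step RK4 scheme and daily conventions as the 2-D model
    (intake and drug effect frozen per day interval; integration
    restarted at day boundaries).  Fat-free mass is recovered by mass
    balance at every grid point.

    Raises
    ------
    ValueError
        If fat mass leaves the physical range (below 0 g or above the
        body-weight input), reporting the time of violation.
    """
    if p.rho_fm == p.rho_ffm:
        raise ZeroDivisionError("rho_fm == rho_ffm: alpha-free model degenerate")
    t0 = int(sched.start_day if t_start is None else round(t_start))
    if t_end is None:
        t_end = sched.end_day
    t_end = int(round(t_end))
    if t_end <= t0:
        raise ValueError("t_end must exceed t_start")
    sched.slice_values(t0, t_end)
    bw0 = float(sbw.bw_on(float(t0), t0))
    if not init_fm < bw0:
        raise ValueError(f"initial fat mass {init_fm} g must be below BW(t0) = {bw0:.1f} g")

    steps = int(steps_per_day)
    h = 1.0 / steps
    n_days = t_end - t0
    n = n_days * steps
    t = t0 + np.arange(n + 1) / steps
    fm = np.empty(n + 1)
    fm[0] = init_fm
    bw = np.empty(n + 1)
    ee = np.empty(n + 1)
    diag = np.empty(n + 1)
    r = p.rho_fm - p.rho_ffm

    def stage(fm_val, tt, day, intake, d):
        s = sbw.bw_on(tt, day)
        ds = sbw.dbw_on(tt, day)
        e = _resolve_expenditure(fm_val, intake, s, ds, p, d)
        return (intake - e - p.rho_ffm * ds) / r

    for kday in range(n_days):
        day = t0 + kday
        intake = sched.intake_on(day)
        d = drug_effect(dose, float(day), drug) if drug is not None else 0.0
        base = kday * steps
        for s_i in range(steps):
            i = base + s_i
            ti = t[i]
            bw[i] = sbw.bw_on(ti, day)
            dsi = sbw.dbw_on(ti, day)
            e_i = _resolve_expenditure(fm[i], intake, bw[i], dsi, p, d)
            ee[i] = e_i
            den = intake - e_i - p.rho_ffm * dsi
            num = intake - e_i - p.rho_fm * dsi
            diag[i] = -num / den if abs(den) >= 1e-8 else np.nan
            k1 = stage(fm[i], ti, day, intake, d)
            k2 = stage(fm[i] + 0.5 * h * k1, ti + 0.5 * h, day, intake, d)
            k3 = stage(fm[i] + 0.5 * h * k2, ti + 0.5 * h, day, intake, d)
            k4 = stage(fm[i] + h * k3, ti + h, day, intake, d)
            fm[i + 1] = fm[i] + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            bw_next = sbw.bw_on(t[i + 1], day)
            if fm[i + 1] < 0.0 or fm[i + 1] > bw_next:
                raise ValueError(
                    f"fat mass left [0, BW] at t={t[i + 1]:.2f} "
                    f"(fm={fm[i + 1]:.2f} g, bw={bw_next:.2f} g)"
                )
    # final grid point: evaluated on the last day's branch
    last_day = t_end - 1
    intake = sched.intake_on(last_day)
    d = drug_effect(dose, float(last_day), drug) if drug is not None else 0.0
    bw[n] = sbw.bw_on(t[n], last_day)
    dsn = sbw.dbw_on(t[n], last_day)
    e_n = _resolve_expenditure(fm[n], intake, bw[n], dsn, p, d)
    ee[n] = e_n
    den = intake - e_n - p.rho_ffm * dsn
    num = intake - e_n - p.rho_fm * dsn
    diag[n] = -num / den if abs(den) >= 1e-8 else np.nan
    return AlphaFreeTrajectory(t, fm, bw - fm, bw, ee, diag, steps, t0)
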