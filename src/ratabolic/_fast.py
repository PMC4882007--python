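"""Closed-form composition of the fixed-step RK4 day map.

Within one day the intake, the drug effect and (for a day-wise profile)
the partition slope are constant, and both simulators' right-hand sides
are *affine in the state*:

* two-compartment model: along the partition line the state collapses to
  fat mass with ``dFM/dt = a*FM + b_day``;
* alpha-free model at a fixed body-weight input: ``dFM/dt = a*FM + b(t)``
  with ``b`` evaluated at the RK4 stage times.

A classical RK4 step applied to an affine ODE is itself an affine map,
so the ``steps_per_day`` substeps compose into a single map per day that
can be evaluated exactly with a handful of vectorised array operations.
Calibration (scalar minimisation, simulated annealing, error surfaces)
uses these routines; they reproduce the general integrator in
``ratabolic.model``/``ratabolic.alphafree`` to floating-point precision,
which the test suite asserts.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = [
    "rk4_factor",
    "partition_day_coeffs",
    "partition_day_values",
    "AlphaFreePath",
]

_A_TINY = 1e-13


def rk4_factor(z):
    """Amplification of one RK4 step for ``dx/dt = a*x`` with ``z = a*h``."""
    return 1.0 + z + z**2 / 2.0 + z**3 / 6.0 + z**4 / 24.0


def partition_day_coeffs(
    p: ModelParams,
    intake: np.ndarray,
    drug: np.ndarray | float,
    i0: np.ndarray | float,
    fm0: np.ndarray | float,
    ffm0: np.ndarray | float,
) -> tuple[float, np.ndarray]:
    """Per-day affine coefficients ``dFM/dt = a*FM + b`` of the 2-D model.

    Along the partition line ``FFM = ffm0 + alpha*(FM - fm0)`` the
    resolved imbalance gives ``dFM/dt = (I - E0(FM)) / (D*(1+c))`` with
    ``E0`` affine in FM, hence a state coefficient ``a`` (shared by all
    days and arms) and a per-day offset ``b``.

    ``intake``/``drug`` may be ``(n_days,)`` or ``(n_days, n_arms)``;
    ``i0``/``fm0``/``ffm0`` scalars or ``(n_arms,)``.
    """
    d_ = p.rho_fm + p.alpha * p.rho_ffm
    c = (p.eta_fm + p.alpha * p.eta_ffm) / d_
    scale = d_ * (1.0 + c)
    q = (p.lam + p.gamma_fm) + p.alpha * (p.lam + p.gamma_ffm)
    a = -q / scale
    line_const = (p.lam + p.gamma_ffm) * (np.asarray(ffm0, float) - p.alpha * np.asarray(fm0, float))
    intake = np.asarray(intake, float)
    b = (
        intake
        - p.k
        - p.beta * (intake - np.asarray(i0, float))
        - np.asarray(drug, float)
        - line_const
    ) / scale
    return a, b


def _compose_constant_a(
    a: float, b: np.ndarray, x0: np.ndarray, amp: float
) -> np.ndarray:
    """Exact composition of n affine maps ``x -> amp*x + s_k`` where each
    map is the RK4 (sub)step aggregate with growth ``amp`` and constant
    term derived from ``b_k``.

    ``b`` has shape ``(n,)`` or ``(n, m)``; returns values at the n+1
    boundaries.  The map constant is ``s_k = (amp - 1) * b_k / a`` (for
    ``a -> 0`` simply ``b_k`` times the interval length, folded into
    ``b`` by the caller).
    """
    b = np.atleast_2d(np.asarray(b, float).T).T  # (n, m)
    n, m = b.shape
    x0 = np.broadcast_to(np.asarray(x0, float), (m,))
    powers = amp ** np.arange(n + 1)[:, None]  # (n+1, 1)
    if abs(a) < _A_TINY:
        incr = np.vstack([np.zeros((1, m)), np.cumsum(b, axis=0)])
        return x0 + incr
    ratio = b / powers[:-1]
    t_sum = np.vstack([np.zeros((1, m)), np.cumsum(ratio, axis=0)])
    return powers * x0 + (amp - 1.0) / a * (powers / amp) * t_sum


def partition_day_values(
    p: ModelParams,
    intake: np.ndarray,
    drug: np.ndarray | float,
    i0: np.ndarray | float,
    fm0: np.ndarray | float,
    ffm0: np.ndarray | float,
    steps_per_day: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact RK4 day-boundary values (FM, FFM, BW) of the 2-D model.

    Matches :func:`ratabolic.model.simulate` at integer days to float
    precision.  Shapes: ``intake`` ``(n_days,)`` or ``(n_days, n_arms)``;
    returns ``(n_days+1, n_arms)`` arrays.
    """
    a, b = partition_day_coeffs(p, intake, drug, i0, fm0, ffm0)
    h = 1.0 / steps_per_day
    amp = float(rk4_factor(a * h) ** steps_per_day)
    fm = _compose_constant_a(a, b, fm0, amp)
    fm0_b = np.broadcast_to(np.asarray(fm0, float), fm.shape[1:])
    ffm0_b = np.broadcast_to(np.asarray(ffm0, float), fm.shape[1:])
    ffm = ffm0_b + p.alpha * (fm - fm0_b)
    return fm, ffm, fm + ffm


class AlphaFreePath:
    """Pre-compiled alpha-free RK4 path for repeated parameter evaluation.

    Freezes everything that does not change during a drug-parameter fit
    (the body-weight input evaluated at all RK4 stage times, the
    state coefficient, the stage weights) so that evaluating the fat-mass
    path for a new ``(k, d)`` is a few vector operations.

    Parameters
    ----------
    p : ModelParams
        Full parameter set; ``p.k`` is *ignored* here (passed per call).
    s_stage, ds_stage : ndarray, shape (n_steps, 3)
        Body weight and its derivative at the RK4 stage times
        ``(t, t+h/2, t+h)`` of every substep.
    intake_step : ndarray, shape (n_steps,)
        Daily intake mapped onto substeps.
    i0 : float
        Baseline intake of the arm.
    fm0 : float
        Initial fat mass at the first grid point.
    steps_per_day : int
    """

    def __init__(
        self,
        p: ModelParams,
        s_stage: np.ndarray,
        ds_stage: np.ndarray,
        intake_step: np.ndarray,
        i0: float,
        fm0: float,
        steps_per_day: int = 10,
    ) -> None:
        r = p.rho_fm - p.rho_ffm
        if r == 0.0:
            raise ZeroDivisionError("rho_fm == rho_ffm: alpha-free model degenerate")
        den = r + p.eta_fm - p.eta_ffm  # r * (1 + c')
        if den == 0.0:
            raise ZeroDivisionError("1 + c' = 0; expenditure undefined")
        g = p.gamma_fm - p.gamma_ffm
        self.a = -g / den
        h = 1.0 / steps_per_day
        self.h = h
        z = self.a * h
        self.amp = float(rk4_factor(z))
        w1 = 1.0 + z + z**2 / 2.0 + z**3 / 4.0
        w2 = 4.0 + 2.0 * z + z**2 / 2.0
        w3 = 1.0
        intake_col = np.asarray(intake_step, float)[:, None]
        # b(t) with k = d = 0; shape (n_steps, 3)
        b0 = (
            intake_col * (1.0 - p.beta)
            + p.beta * i0
            - (p.rho_ffm + p.eta_ffm) * ds_stage
            - (p.lam + p.gamma_ffm) * s_stage
        ) / den
        self.b_base = (h / 6.0) * (w1 * b0[:, 0] + w2 * b0[:, 1] + w3 * b0[:, 2])
        self.w_const = (h / 6.0) * (w1 + w2 + w3) / den
        self.fm0 = float(fm0)
        self.steps_per_day = steps_per_day
        n = len(self.b_base)
        self.powers = self.amp ** np.arange(n + 1)

    def fm_path(self, k: float, d_step: np.ndarray | float) -> np.ndarray:
        """Fat mass at every substep boundary for basal offset ``k`` and
        per-substep drug effect ``d_step`` (scalar or ``(n_steps,)``)."""
        b = self.b_base - (k + np.asarray(d_step, float)) * self.w_const
        if abs(self.a) < _A_TINY:
            return self.fm0 + np.concatenate([[0.0], np.cumsum(b)])
        ratio = b / self.powers[:-1]
        t_sum = np.concatenate([[0.0], np.cumsum(ratio)])
        return self.powers * self.fm0 + (self.powers / self.amp) * t_sum

    def fm_at_days(self, k: float, d_step) -> np.ndarray:
        """Fat mass at integer-day boundaries."""
        return self.fm_path(k, d_step)[:: self.steps_per_day]
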