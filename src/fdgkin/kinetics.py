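"""Compartmental models of pulmonary ¹⁸F-FDG kinetics and their algebra.

Two linear compartment models are simulated against a plasma input function
C_p(t):

* the Sokoloff three-compartment model (blood, extra-vascular precursor C_e,
  metabolized/trapped C_m)::

      dC_e/dt = k1*C_p - (k2 + k3)*C_e
      dC_m/dt = k3*C_e

* the lung-specific four-compartment model, which adds an extra-vascular
  extra-cellular (non-substrate) compartment C_ee exchanging with the
  precursor pool::

      dC_e/dt  = k1*C_p - (k2 + k3 + k5)*C_e + k6*C_ee
      dC_ee/dt = k5*C_e - k6*C_ee
      dC_m/dt  = k3*C_e

The measurable ROI activity is C_ROI(t) = F_B*C_p(t) + C_e + C_m (+ C_ee), and
a PET frame records the time-average of C_ROI over the frame.

Integration is explicit forward Euler at a fixed step (default 0.1 s), with
all compartments starting at zero.  The Euler recursion is evaluated exactly
as a linear constant-coefficient difference equation via ``scipy.signal
.lfilter`` — the same sequence a per-step loop would produce, computed in one
vectorized pass.

Derived quantities:

* net uptake rate  Ki = k1*k3/(k2 + k3)   (1/min)
* precursor distribution volume  F_e (= F_ei for the four-compartment model)
  = k1/(k2 + k3), so that F_e * k3 = Ki identically
* extra-vascular extra-cellular distribution volume  F_ee = F_ei * k5/k6
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .models import (
    SEC_PER_MIN,
    CompartmentTrajectory,
    FourCompParams,
    FrameSchedule,
    InputFunction,
    SokoloffParams,
    TimeActivityCurve,
)

__all__ = [
    "simulate",
    "euler_compartments",
    "frame_average",
    "ki_irreversible",
    "fe_fraction",
    "fee_fraction",
]


class SimulationError(RuntimeError):
    """Raised when the forward Euler integration is unusable (instability)."""


def ki_irreversible(k1: float, k2: float, k3: float) -> float:
    """Net uptake rate Ki = k1*k3/(k2+k3) of an irreversible tracer, 1/min.

    The same expression gives Ki_S for the Sokoloff model and Ki_F for the
    four-compartment model: in quasi-steady state the extra-cellular
    compartment is in equilibrium with the precursor pool and does not alter
    the net flux into the trapped compartment.
    """
    if k2 + k3 <= 0.0:
        raise ValueError("Ki undefined: k2 + k3 must be > 0")
    return k1 * k3 / (k2 + k3)


def fe_fraction(k1: float, k2: float, k3: float) -> float:
    """Fractional distribution volume of the precursor compartment, k1/(k2+k3)."""
    if k2 + k3 <= 0.0:
        raise ValueError("F_e undefined: k2 + k3 must be > 0")
    return k1 / (k2 + k3)


def fee_fraction(params: FourCompParams) -> float:
    """Extra-vascular extra-cellular distribution volume F_ee = F_ei * k5/k6."""
    if params.k5 == 0.0:
        return 0.0
    if params.k6 <= 0.0:
        raise ValueError("F_ee undefined: k6 must be > 0 when k5 > 0")
    return fe_fraction(params.k1, params.k2, params.k3) * params.k5 / params.k6


def euler_compartments(
    cp: np.ndarray, step_s: float, k1: float, k2: float, k3: float,
    k5: float = 0.0, k6: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-Euler compartment activities on a uniform grid carrying ``cp``.

    Returns (C_e, C_m, C_ee) sampled at the same grid points as ``cp``.  The
    Euler update with step h (minutes) is

        C_e[n+1]  = C_e[n]  + h*(k1*C_p[n] - (k2+k3+k5)*C_e[n] + k6*C_ee[n])
        C_ee[n+1] = C_ee[n] + h*(k5*C_e[n] - k6*C_ee[n])
        C_m[n+1]  = C_m[n]  + h*k3*C_e[n]

    which, eliminating C_ee, is the second-order difference equation realised
    below with ``lfilter`` (b/a are the z-transform numerator/denominator of
    the recursion; identical sequence, no approximation beyond Euler itself).
    """
    h = step_s / SEC_PER_MIN
    alpha = 1.0 - (k2 + k3 + k5) * h
    beta = 1.0 - k6 * h
    with np.errstate(over="ignore", invalid="ignore"):  # instability raised below
        if k5 > 0.0:
            den = np.array([1.0, -(alpha + beta), alpha * beta - k5 * k6 * h * h])
            c_e = lfilter([0.0, k1 * h, -k1 * h * beta], den, cp)
            c_ee = lfilter([0.0, 0.0, k1 * k5 * h * h], den, cp)
        else:
            # k5 = 0 decouples C_ee (identically zero from zero initial state);
            # use the scalar recursion so the reduction to the three-compartment
            # model is exact, not up to pole-zero cancellation round-off
            c_e = lfilter([0.0, k1 * h], [1.0, -alpha], cp)
            c_ee = np.zeros_like(c_e)
        c_m = np.empty_like(c_e)
        c_m[0] = 0.0
        np.cumsum(c_e[:-1], out=c_m[1:])
        c_m *= k3 * h

    scale = float(np.max(np.abs(c_e), initial=0.0)) + float(np.max(cp, initial=0.0))
    bad = min(float(c_e.min()), float(c_ee.min()), 0.0)
    if not np.all(np.isfinite(c_e)) or bad < -1e-9 * max(scale, 1e-300):
        raise SimulationError(
            f"Euler integration unstable at step {step_s} s "
            f"(negative/non-finite compartment activity; rates k2+k3+k5="
            f"{k2 + k3 + k5:g}, k6={k6:g} 1/min). Reduce the step."
        )
    return c_e, c_m, c_ee


def frame_average(values: np.ndarray, time_s: np.ndarray,
                  schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a densely sampled signal over each PET frame.

    Uses the trapezoidal cumulative integral of ``values`` on ``time_s`` and
    differences it at the frame edges, reflecting that a PET frame records
    counts integrated over the frame interval.
    """
    cum = cumulative_trapezoid(values, time_s, initial=0.0)
    upper = np.interp(schedule.end, time_s, cum)
    lower = np.interp(schedule.start, time_s, cum)
    return (upper - lower) / schedule.duration


def _grid_for(schedule: FrameSchedule, step_s: float) -> np.ndarray:
    total = schedule.total_duration_s
    n = int(round(total / step_s))
    if abs(n * step_s - total) > 1e-6:
        raise ValueError(
            f"integrator step {step_s} s must divide the schedule duration {total} s"
        )
    return np.arange(n + 1) * step_s


def simulate(
    params: SokoloffParams | FourCompParams,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    step: float = 0.1,
) -> tuple[TimeActivityCurve, CompartmentTrajectory]:
    """Forward-simulate a ROI time-activity curve from model parameters.

    Parameters
    ----------
    params
        Sokoloff or four-compartment rate constants (1/min) and fractional
        blood volume.
    input_fn
        Plasma input function; must cover the whole schedule.
    schedule
        PET frame timing; frame values are within-frame time-averages of the
        instantaneous ROI activity.
    step
        Euler step in seconds; must be positive, no longer than the shortest
        frame, and divide the total acquisition time.

    Returns
    -------
    (TimeActivityCurve, CompartmentTrajectory)
        The frame-averaged observable and the dense compartment activities.
    """
    if step <= 0.0:
        raise ValueError("step must be > 0")
    if step > float(np.min(schedule.duration)):
        raise ValueError("step must not exceed the shortest frame duration")
    if not input_fn.covers(schedule.total_duration_s):
        raise ValueError("input function does not cover the frame schedule")

    t = _grid_for(schedule, step)
    cp = input_fn(t)
    k5 = getattr(params, "k5", 0.0)
    k6 = getattr(params, "k6", 0.0)
    c_e, c_m, c_ee = euler_compartments(cp, step, params.k1, params.k2,
                                        params.k3, k5, k6)
    roi = params.fb * cp + c_e + c_m + c_ee
    tac = TimeActivityCurve(
        schedule=schedule,
        activity=frame_average(roi, t, schedule),
        meta={"model": params.to_dict(), "step_s": step},
    )
    traj = CompartmentTrajectory(time=t, c_p=cp, c_e=c_e, c_m=c_m, c_ee=c_ee,
                                 params=params)
    return tac, traj
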