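"""Estimation of ¹⁸F-FDG kinetics parameters from a TAC and an input function.

Three estimators:

* :func:`patlak_fit` — graphical analysis for irreversible tracers: ordinary
  least squares of y(t) = C_ROI(t)/C_p(t) against the "stretched time"
  x(t) = ∫₀ᵗ C_p ds / C_p(t), over frames whose mid-time is at or after a
  configurable start (default 15 min).  The slope is the net uptake rate
  Ki_P; the intercept measures the reversible distribution volume.
* :func:`fit_sokoloff` / :func:`fit_fourcomp` — bound-constrained nonlinear
  least squares of the forward compartment model against the frame-averaged
  TAC, globalized by a multi-start scheme (scrambled Sobol points across the
  parameter box, plus optional caller-supplied warm starts).  The contract is
  global minimisation of the squared frame residuals.
* :func:`aic` — least-squares Akaike information criterion used to compare
  the two compartment models on the same TAC.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.stats import linregress, qmc

from . import kinetics
from .models import (
    SEC_PER_MIN,
    FourCompParams,
    InputFunction,
    SokoloffParams,
    TimeActivityCurve,
)

__all__ = [
    "PatlakResult",
    "FitResult",
    "patlak_fit",
    "fit_sokoloff",
    "fit_fourcomp",
    "aic",
    "DEFAULT_RATE_BOUND",
    "DEFAULT_FB_BOUND",
]

log = logging.getLogger(__name__)

#: Generous physiological envelope for the multi-start search box.
DEFAULT_RATE_BOUND = (0.0, 5.0)   # 1/min, each rate constant
DEFAULT_FB_BOUND = (0.0, 0.5)     # fractional blood volume


@dataclass(frozen=True)
class PatlakResult:
    ki: float            # slope, 1/min
    y_intercept: float   # dimensionless distribution-volume measure
    r_squared: float
    n_points: int
    t_start_min: float

    def to_dict(self) -> dict:
        return {"method": "patlak", "ki_per_min": self.ki,
                "y_intercept": self.y_intercept, "r_squared": self.r_squared,
                "n_points": self.n_points, "t_start_min": self.t_start_min}


@dataclass(frozen=True)
class FitResult:
    params: SokoloffParams | FourCompParams
    sse: float
    aic: float
    n_frames: int
    n_params: int
    converged: bool
    n_starts_used: int

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "sse": self.sse,
                "aic": self.aic, "n_frames": self.n_frames,
                "n_params": self.n_params, "converged": self.converged,
                "n_starts_used": self.n_starts_used}


def aic(sse: float, n_frames: int, n_params: int) -> float:
    """Least-squares AIC: n*ln(sse/n) + 2*(n_params + 1).

    The +1 counts the error variance as an estimated parameter.  Only AIC
    differences between models fitted to the same frames are meaningful.
    """
    if sse <= 0.0:
        raise ValueError("AIC undefined for sse <= 0 (degenerate perfect fit)")
    if n_frames <= n_params:
        raise ValueError("AIC requires n_frames > n_params")
    return n_frames * math.log(sse / n_frames) + 2.0 * (n_params + 1)


def patlak_fit(tac: TimeActivityCurve, input_fn: InputFunction,
               t_start: float = 15.0) -> PatlakResult:
    """Patlak graphical estimate of the net uptake rate.

    ``t_start`` is in minutes; frames whose mid-time falls before it are
    excluded so that the reversible compartments have equilibrated.  The
    abscissa ∫₀ᵗ C_p ds / C_p(t) is computed on the fine input grid
    (trapezoidal cumulative integral, in minutes) and evaluated at frame
    mid-times.
    """
    sched = tac.schedule
    if not input_fn.covers(sched.total_duration_s):
        raise ValueError("input function does not cover the frame schedule")
    mid_s = sched.mid
    mask = mid_s / SEC_PER_MIN >= t_start - 1e-12
    if int(mask.sum()) < 2:
        raise ValueError(
            f"Patlak fit needs >= 2 frames with mid-time >= {t_start} min"
        )
    cp_mid = input_fn(mid_s[mask])
    if np.any(cp_mid <= 0.0):
        raise ValueError("plasma activity must be > 0 at all used frame mid-times")
    cum_min = cumulative_trapezoid(input_fn.activity, input_fn.time,
                                   initial=0.0) / SEC_PER_MIN
    x = np.interp(mid_s[mask], input_fn.time, cum_min) / cp_mid
    y = tac.activity[mask] / cp_mid
    res = linregress(x, y)
    return PatlakResult(ki=float(res.slope), y_intercept=float(res.intercept),
                        r_squared=float(res.rvalue) ** 2,
                        n_points=int(mask.sum()), t_start_min=float(t_start))


def _forward_frames(input_fn, schedule, step, fourcomp: bool):
    """Closure mapping a parameter vector to model frame averages.

    The integrator grid, the interpolated plasma curve and the frame edges
    are precomputed once so repeated objective evaluations stay cheap.
    """
    total = schedule.total_duration_s
    n = int(round(total / step))
    if abs(n * step - total) > 1e-6:
        raise ValueError("step must divide the schedule duration")
    t = np.arange(n + 1) * step
    cp = input_fn(t)

    def frames(theta: np.ndarray) -> np.ndarray:
        fb, k1, k2, k3 = theta[:4]
        k5, k6 = (theta[4], theta[5]) if fourcomp else (0.0, 0.0)
        c_e, c_m, c_ee = kinetics.euler_compartments(cp, step, k1, k2, k3, k5, k6)
        roi = fb * cp + c_e + c_m + c_ee
        return kinetics.frame_average(roi, t, schedule)

    return frames


def _sobol_starts(lb, ub, n_starts, seed):
    sampler = qmc.Sobol(d=lb.size, scramble=True, seed=seed)
    with warnings.catch_warnings():
        # Sobol balance warning for non-power-of-two draws is irrelevant here:
        # the points seed local searches, they are not used for integration.
        warnings.simplefilter("ignore", UserWarning)
        unit = sampler.random(n_starts)
    return lb + unit * (ub - lb)


def _multistart_fit(tac, input_fn, fourcomp, bounds, n_starts, seed, step,
                    extra_starts):
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if bounds is None:
        per_rate = [DEFAULT_RATE_BOUND] * (5 if fourcomp else 3)
        bounds = [DEFAULT_FB_BOUND] + per_rate
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    dim = 6 if fourcomp else 4
    if lb.size != dim or np.any(ub <= lb):
        raise ValueError(f"bounds must be {dim} valid (low, high) pairs")

    frames = _forward_frames(input_fn, tac.schedule, step, fourcomp)
    y = tac.activity
    big = 1e3 * (1.0 + float(np.max(np.abs(y))))

    def resid(theta):
        try:
            return frames(theta) - y
        except kinetics.SimulationError:
            return np.full(y.size, big)

    starts = [np.clip(np.asarray(s, dtype=float), lb, ub)
              for s in (extra_starts or [])]
    starts.extend(_sobol_starts(lb, ub, n_starts, seed))

    best = None  # (sse, k5, params_vector, success)
    any_success = False
    for i, x0 in enumerate(starts):
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                x_scale="jac")
        except Exception:
            log.debug("start %d failed outright from x0=%s", i, x0)
            continue
        any_success = any_success or bool(sol.success)
        sse = float(np.sum(sol.fun ** 2))
        log.debug("start %d: success=%s sse=%.6g nfev=%d", i, sol.success,
                  sse, sol.nfev)
        k5_val = float(sol.x[4]) if fourcomp else 0.0
        key = (sse, k5_val)
        if best is None or key < best[0]:
            best = (key, sol.x.copy())
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    x = best[1]
    if fourcomp:
        if x[4] > 0.0 and x[5] <= 0.0:
            # optimizer pinned k6 at the zero bound with k5 free: an
            # extra-cellular pool that only accumulates behaves as a second
            # trap and F_ee is undefined; report the nested model instead.
            x[4] = 0.0
            x[5] = 0.0
            best = ((float(np.sum(resid(x) ** 2)), 0.0), x)
        params = FourCompParams(fb=float(x[0]), k1=float(x[1]), k2=float(x[2]),
                                k3=float(x[3]), k5=float(x[4]), k6=float(x[5]))
    else:
        params = SokoloffParams(fb=float(x[0]), k1=float(x[1]), k2=float(x[2]),
                                k3=float(x[3]))
    sse = best[0][0]
    n_frames = y.size
    n_params = dim
    aic_val = aic(sse, n_frames, n_params) if sse > 0.0 else -math.inf
    return FitResult(params=params, sse=sse, aic=aic_val, n_frames=n_frames,
                     n_params=n_params, converged=any_success,
                     n_starts_used=len(starts))


def fit_sokoloff(tac: TimeActivityCurve, input_fn: InputFunction, *,
                 bounds=None, n_starts: int = 32, seed: int = 0,
                 step: float = 0.5, extra_starts=None) -> FitResult:
    """Multi-start least-squares fit of the Sokoloff model (fb, k1, k2, k3).

    ``bounds`` is a sequence of (low, high) pairs ordered (fb, k1, k2, k3);
    defaults to fb in [0, 0.5] and each rate in [0, 5]/min.  ``extra_starts``
    are optional warm-start vectors prepended to the Sobol points.  The
    result is deterministic for a fixed seed, and the best SSE is
    non-increasing in ``n_starts`` (Sobol draws are prefix-nested).
    """
    return _multistart_fit(tac, input_fn, False, bounds, n_starts, seed, step,
                           extra_starts)


def fit_fourcomp(tac: TimeActivityCurve, input_fn: InputFunction, *,
                 bounds=None, n_starts: int = 32, seed: int = 0,
                 step: float = 0.5, extra_starts=None) -> FitResult:
    """Multi-start least-squares fit of the four-compartment model.

    As :func:`fit_sokoloff`, over (fb, k1, k2, k3, k5, k6).  Exactly tied
    starts are broken toward the lower k5 (parsimony: prefer the smaller
    extra-cellular exchange when the data cannot distinguish them).
    """
    return _multistart_fit(tac, input_fn, True, bounds, n_starts, seed, step,
                           extra_starts)
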