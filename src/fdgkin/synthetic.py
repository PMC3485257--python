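"""Synthetic plasma input functions, frame schedules and ground-truth kinetics.

The generators emulate the acquisition conditions of a 75-min dynamic
¹⁸F-FDG lung PET study: a 60-s constant-rate intravenous infusion, a 32-frame
schedule (6×30 s, 7×60 s, 15×120 s, 1×300 s, 3×600 s), and rate-constant sets
for two representative lung regions — a healthy non-dependent region
("LPS-Lav-") and a severely injured dependent region after endotoxin plus
bronchoalveolar lavage ("LPS+Lav+").

The plasma input is a 60-s box (constant-rate infusion) convolved with a
tri-exponential clearance, a standard FDG plasma shape; its closed form is
evaluated exactly on the output grid.  Amplitude is arbitrary: every
estimator in this package is invariant to the input-function scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .models import (
    SEC_PER_MIN,
    FourCompParams,
    FrameSchedule,
    InputFunction,
    SokoloffParams,
    TimeActivityCurve,
)

__all__ = [
    "DEFAULT_CLEARANCE",
    "CONDITIONS",
    "make_default_schedule",
    "make_input_function",
    "table1_params",
    "add_noise",
]

#: Default tri-exponential plasma clearance: (rate 1/min, fraction) pairs.
#: Fast redistribution, intermediate exchange, and a slow terminal phase;
#: chosen so the curve peaks at the end of the 60-s infusion and decays to
#: roughly 10% of peak by 75 min.
DEFAULT_CLEARANCE: tuple[tuple[float, float], ...] = (
    (2.0, 0.75),
    (0.12, 0.15),
    (0.008, 0.10),
)

CONDITIONS = ("LPS-Lav-", "LPS+Lav+")

# Representative regional parameter estimates for the two study conditions
# (rates in 1/min after scale conversion; fb dimensionless).
_TABLE1 = {
    "LPS-Lav-": {
        "sokoloff": dict(fb=0.07, k1=0.013, k2=0.25, k3=0.0177),
        "fourcomp": dict(fb=0.04, k1=0.100, k2=1.94, k3=0.0143, k5=0.07, k6=0.11),
    },
    "LPS+Lav+": {
        "sokoloff": dict(fb=0.09, k1=0.088, k2=0.12, k3=0.0308),
        "fourcomp": dict(fb=0.07, k1=0.113, k2=0.23, k3=0.0368, k5=0.04, k6=0.06),
    },
}


def make_default_schedule() -> FrameSchedule:
    """The 32-frame, 75-min acquisition: 6×30 s, 7×60 s, 15×120 s, 1×300 s, 3×600 s."""
    durations = [30.0] * 6 + [60.0] * 7 + [120.0] * 15 + [300.0] + [600.0] * 3
    return FrameSchedule.from_durations(durations)


def make_input_function(
    amplitude: float = 1.0,
    infusion_duration: float = 60.0,
    clearance_rates=DEFAULT_CLEARANCE,
    grid_step: float = 1.0,
    t_end: float = 4500.0,
) -> InputFunction:
    """Plasma input: constant-rate infusion convolved with multi-exponential clearance.

    Parameters
    ----------
    amplitude
        Peak plasma activity (arbitrary units); the whole curve scales
        linearly with it, and ``amplitude = 0`` gives the zero curve.
    infusion_duration
        Infusion length in seconds; the curve rises on [0, T] and peaks at T.
    clearance_rates
        Sequence of ``(rate_per_min, fraction)`` pairs; fractions must sum to
        1 and rates must be > 0.
    grid_step
        Output grid spacing in seconds.
    t_end
        Last grid time in seconds (default covers the 75-min acquisition).

    The closed form of the box/exponential convolution is, with T the
    infusion duration in minutes and τ = t/60::

        C_p(t) ∝ Σ_i f_i/λ_i * (1 - exp(-λ_i*min(τ,T))) * exp(-λ_i*max(τ-T,0))
    """
    if amplitude < 0.0:
        raise ValueError("amplitude must be >= 0")
    if infusion_duration <= 0.0:
        raise ValueError("infusion_duration must be > 0")
    if grid_step <= 0.0:
        raise ValueError("grid_step must be > 0")
    rates = np.array([r for r, _ in clearance_rates], dtype=float)
    fracs = np.array([f for _, f in clearance_rates], dtype=float)
    if np.any(rates <= 0.0):
        raise ValueError("all clearance rates must be > 0")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("clearance fractions must sum to 1")

    t = np.arange(0.0, t_end + 0.5 * grid_step, grid_step)
    tau = t / SEC_PER_MIN
    big_t = infusion_duration / SEC_PER_MIN
    rise = 1.0 - np.exp(-rates[:, None] * np.minimum(tau, big_t)[None, :])
    decay = np.exp(-rates[:, None] * np.maximum(tau - big_t, 0.0)[None, :])
    shape = ((fracs / rates)[:, None] * rise * decay).sum(axis=0)
    peak = shape.max()
    activity = amplitude * shape / peak if peak > 0.0 else np.zeros_like(shape)
    meta = {
        "generator": "box_infusion_multiexp",
        "amplitude": amplitude,
        "infusion_duration_s": infusion_duration,
        "clearance_rates_per_min": [list(p) for p in clearance_rates],
        "grid_step_s": grid_step,
        "t_end_s": t_end,
    }
    return InputFunction(time=t, activity=activity, meta=meta)


def table1_params(condition: str, model: str) -> SokoloffParams | FourCompParams:
    """Ground-truth rate constants for one study condition and model.

    ``condition`` is one of ``"LPS-Lav-"`` (healthy non-dependent region) or
    ``"LPS+Lav+"`` (endotoxin + lavage, dependent region); ``model`` is
    ``"sokoloff"`` or ``"fourcomp"``. Rates are returned in 1/min.
    """
    try:
        fields = _TABLE1[condition][model]
    except KeyError:
        raise ValueError(
            f"unknown condition/model {condition!r}/{model!r}; conditions: "
            f"{CONDITIONS}, models: ('sokoloff', 'fourcomp')"
        ) from None
    cls = SokoloffParams if model == "sokoloff" else FourCompParams
    return cls(**fields)


def add_noise(tac: TimeActivityCurve, noise_scale: float, seed: int) -> TimeActivityCurve:
    """Add zero-mean Gaussian noise with variance ∝ activity / frame duration.

    This is the standard PET count-statistics weighting: longer frames and
    lower activities give lower variance.  ``noise_scale = 0`` returns the
    TAC unchanged.  Not part of the noiseless estimator-error study; intended
    for robustness testing.
    """
    if noise_scale < 0.0:
        raise ValueError("noise_scale must be >= 0")
    if noise_scale == 0.0:
        return tac
    rng = np.random.default_rng(seed)
    dur_min = tac.schedule.duration / SEC_PER_MIN
    sigma = noise_scale * np.sqrt(np.maximum(tac.activity, 0.0) / dur_min)
    noisy = tac.activity + rng.normal(0.0, 1.0, tac.activity.size) * sigma
    meta = dict(tac.meta)
    meta.update({"noise_scale": noise_scale, "noise_seed": seed})
    return replace(tac, activity=noisy, meta=meta)
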