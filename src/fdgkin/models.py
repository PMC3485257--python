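"""Domain containers for pulmonary ¹⁸F-FDG kinetic modelling.

Conventions used throughout the package:

* schedules and time grids are in **seconds** from the start of the tracer
  infusion;
* all rate constants (k1, k2, k3, k5, k6) are in **1/min**;
* activity is in arbitrary units per mL (every estimator here is invariant to
  the absolute activity scale);
* fractional volumes (F_B, F_e, F_ei, F_ee) are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

SEC_PER_MIN = 60.0

__all__ = [
    "SEC_PER_MIN",
    "FrameSchedule",
    "InputFunction",
    "TimeActivityCurve",
    "SokoloffParams",
    "FourCompParams",
    "CompartmentTrajectory",
]


def _as_float_array(x: Any) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D array")
    return arr


@dataclass(frozen=True)
class FrameSchedule:
    """PET frame timing: per-frame start times and durations in seconds.

    Frames must be contiguous and non-overlapping, starting at t = 0, so the
    schedule partitions [0, total_duration_s] exactly.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = _as_float_array(self.start)
        duration = _as_float_array(self.duration)
        if start.size == 0 or start.size != duration.size:
            raise ValueError("schedule needs equal, non-empty start/duration arrays")
        if start[0] != 0.0:
            raise ValueError("first frame must start at 0 s")
        if np.any(duration <= 0.0):
            raise ValueError("all frame durations must be > 0")
        gaps = start[1:] - (start[:-1] + duration[:-1])
        if np.any(gaps > 1e-9):
            raise ValueError("frame gap detected: frames must be contiguous")
        if np.any(gaps < -1e-9):
            raise ValueError("frame overlap detected: frames must not overlap")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        durations = _as_float_array(durations)
        start = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
        return cls(start=start, duration=durations)

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def mid(self) -> np.ndarray:
        return self.start + 0.5 * self.duration

    @property
    def total_duration_s(self) -> float:
        return float(self.end[-1])


@dataclass(frozen=True)
class InputFunction:
    """Plasma tracer activity C_p(t) on a fine, strictly increasing time grid."""

    time: np.ndarray  # seconds
    activity: np.ndarray  # arbitrary activity units / mL
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        time = _as_float_array(self.time)
        activity = _as_float_array(self.activity)
        if time.size != activity.size or time.size < 2:
            raise ValueError("input function needs >= 2 matching time/activity samples")
        if np.any(np.diff(time) <= 0.0):
            raise ValueError("input-function time grid must be strictly increasing")
        if np.any(~np.isfinite(activity)) or np.any(activity < 0.0):
            raise ValueError("input-function activity must be finite and non-negative")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "activity", activity)

    def __call__(self, t) -> np.ndarray:
        """Linearly interpolated plasma activity at time(s) ``t`` (seconds)."""
        return np.interp(t, self.time, self.activity)

    def covers(self, t_end_s: float) -> bool:
        return self.time[0] <= 1e-9 and self.time[-1] >= t_end_s - 1e-9


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged ROI activity on a :class:`FrameSchedule`."""

    schedule: FrameSchedule
    activity: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        activity = _as_float_array(self.activity)
        if activity.size != self.schedule.n_frames:
            raise ValueError("TAC length must equal the number of frames")
        if np.any(~np.isfinite(activity)):
            raise ValueError("TAC activities must be finite")
        object.__setattr__(self, "activity", activity)


def _check_rates(**rates: float) -> None:
    for name, value in rates.items():
        if not np.isfinite(value) or value < 0.0:
            raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class SokoloffParams:
    """Three-compartment (blood, precursor, metabolized) model parameters.

    fb is the fractional blood volume; k1/k2 exchange the precursor compartment
    with plasma; k3 is the phosphorylation (trapping) rate. All rates in 1/min.
    """

    fb: float
    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        _check_rates(k1=self.k1, k2=self.k2, k3=self.k3)
        if not 0.0 <= self.fb <= 1.0:
            raise ValueError(f"fb must be in [0, 1], got {self.fb!r}")

    def to_dict(self) -> dict:
        return {"model": "sokoloff", "fb": self.fb, "k1": self.k1,
                "k2": self.k2, "k3": self.k3}


@dataclass(frozen=True)
class FourCompParams:
    """Lung-specific four-compartment model parameters.

    Extends the Sokoloff parameters with k5/k6, the forward/backward exchange
    rates between the precursor compartment and the extra-vascular
    extra-cellular (non-substrate) compartment.
    """

    fb: float
    k1: float
    k2: float
    k3: float
    k5: float
    k6: float

    def __post_init__(self) -> None:
        _check_rates(k1=self.k1, k2=self.k2, k3=self.k3, k5=self.k5, k6=self.k6)
        if not 0.0 <= self.fb <= 1.0:
            raise ValueError(f"fb must be in [0, 1], got {self.fb!r}")
        if self.k5 > 0.0 and self.k6 <= 0.0:
            raise ValueError("k6 must be > 0 whenever k5 > 0 (F_ee = F_ei*k5/k6)")

    def to_dict(self) -> dict:
        return {"model": "fourcomp", "fb": self.fb, "k1": self.k1, "k2": self.k2,
                "k3": self.k3, "k5": self.k5, "k6": self.k6}

    def drop_ee(self) -> SokoloffParams:
        """The nested Sokoloff parameter set (same fb, k1, k2, k3)."""
        return SokoloffParams(fb=self.fb, k1=self.k1, k2=self.k2, k3=self.k3)


def params_from_dict(d: dict) -> "SokoloffParams | FourCompParams":
    """Inverse of ``to_dict`` for either parameter variant."""
    kind = d.get("model")
    fields = {k: float(v) for k, v in d.items() if k != "model"}
    if kind == "sokoloff":
        return SokoloffParams(**fields)
    if kind == "fourcomp":
        return FourCompParams(**fields)
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass(frozen=True)
class CompartmentTrajectory:
    """Dense compartment activities from a forward simulation.

    c_e: extra-vascular precursor; c_m: metabolized (trapped); c_ee:
    extra-vascular extra-cellular (identically zero for the Sokoloff model);
    c_p: plasma input sampled on the integrator grid. All per unit ROI volume,
    in input-function activity units.
    """

    time: np.ndarray  # seconds, uniform integrator grid
    c_p: np.ndarray
    c_e: np.ndarray
    c_m: np.ndarray
    c_ee: np.ndarray
    params: "SokoloffParams | FourCompParams"

    @property
    def roi_activity(self) -> np.ndarray:
        """Total measurable ROI activity F_B*C_p + C_e + C_m + C_ee."""
        return self.params.fb * self.c_p + self.c_e + self.c_m + self.c_ee


def with_params(params, **changes):
    """dataclasses.replace that works for both parameter variants."""
    return replace(params, **changes)
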