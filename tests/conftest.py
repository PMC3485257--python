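"""Shared fixtures: default acquisition objects and the full error sweep.

The 9x9x2 default sweep is expensive (a few minutes), so it is computed once
per session and shared by the error-study and acceptance tests.
"""

import numpy as np
import pytest

import fdgkin as fk


@pytest.fixture(scope="session")
def schedule():
    return fk.make_default_schedule()


@pytest.fixture(scope="session")
def input_fn():
    return fk.make_input_function()


@pytest.fixture(scope="session")
def default_sweep():
    """Full default estimator-error sweep (both conditions, 9x9 grid)."""
    return fk.run_sweep(seed=0)


@pytest.fixture(scope="session")
def small_sweep_spec():
    return fk.SweepSpec(n_steps=3, conditions=("LPS+Lav+",))


def zoh_expm_tac(params, input_fn, schedule, step):
    """Independent oracle: exact solution for piecewise-constant plasma input.

    Discretizes the continuous-time linear system with a matrix exponential
    (zero-order hold on C_p over each step) and steps the exact state
    transition; shares nothing with the forward-Euler implementation except
    the frame-averaging convention.
    """
    from scipy.linalg import expm

    from fdgkin.kinetics import frame_average

    k5 = getattr(params, "k5", 0.0)
    k6 = getattr(params, "k6", 0.0)
    A = np.array([[-(params.k2 + params.k3 + k5), k6, 0.0],
                  [k5, -k6, 0.0],
                  [params.k3, 0.0, 0.0]])
    B = np.array([params.k1, 0.0, 0.0])
    h = step / 60.0
    M = expm(np.block([[A * h, (B * h)[:, None]], [np.zeros((1, 4))]]))
    Ad, Bd = M[:3, :3], M[:3, 3]
    n = int(round(schedule.total_duration_s / step))
    t = np.arange(n + 1) * step
    cp = input_fn(t)
    states = np.zeros((n + 1, 3))
    x = np.zeros(3)
    for i in range(n):
        x = Ad @ x + Bd * cp[i]
        states[i + 1] = x
    roi = params.fb * cp + states.sum(axis=1)
    return frame_average(roi, t, schedule)
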