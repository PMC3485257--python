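"""Patlak graphical analysis, nonlinear model fits, and AIC comparison."""

import math

import numpy as np
import pytest

import fdgkin as fk
from fdgkin.models import FrameSchedule, TimeActivityCurve


def _frame_avg_of(fn, schedule, step=0.5):
    t = np.arange(0.0, schedule.total_duration_s + 0.5 * step, step)
    from fdgkin.kinetics import frame_average
    return frame_average(fn(t), t, schedule)


class TestPatlak:
    def test_exact_irreversible_form_recovered(self, schedule, input_fn):
        # C_ROI(t) = K * ∫C_p: slope K, zero intercept, to numerical precision
        from scipy.integrate import cumulative_trapezoid
        K = 1e-3  # 1/min
        cum = cumulative_trapezoid(input_fn.activity, input_fn.time, initial=0.0) / 60.0
        tac = TimeActivityCurve(
            schedule=schedule,
            activity=_frame_avg_of(lambda t: K * np.interp(t, input_fn.time, cum),
                                   schedule))
        res = fk.patlak_fit(tac, input_fn)
        assert res.ki == pytest.approx(K, rel=1e-3)
        assert abs(res.y_intercept) < 1e-4
        assert res.r_squared > 0.999999

    def test_pure_distribution_volume(self, schedule, input_fn):
        V = 0.2
        tac = TimeActivityCurve(schedule=schedule,
                                activity=_frame_avg_of(lambda t: V * input_fn(t),
                                                       schedule))
        res = fk.patlak_fit(tac, input_fn)
        assert abs(res.ki) < 1e-6
        assert res.y_intercept == pytest.approx(V, rel=1e-2)

    def test_slope_near_ki_for_irreversible_model(self, schedule, input_fn):
        p = fk.table1_params("LPS+Lav+", "sokoloff")
        tac, _ = fk.simulate(p, input_fn, schedule, step=0.1)
        ki = fk.ki_irreversible(p.k1, p.k2, p.k3)
        res = fk.patlak_fit(tac, input_fn)
        assert res.ki == pytest.approx(ki, rel=0.05)

    def test_slope_converges_with_scan_duration(self):
        # the residual transient bias vanishes as the scan extends (4x duration)
        p = fk.table1_params("LPS+Lav+", "sokoloff")
        ki = fk.ki_irreversible(p.k1, p.k2, p.k3)
        sched4 = FrameSchedule.from_durations([120.0] * 150)
        inp4 = fk.make_input_function(t_end=18000.0)
        tac4, _ = fk.simulate(p, inp4, sched4, step=0.5)
        res4 = fk.patlak_fit(tac4, inp4)
        assert res4.ki == pytest.approx(ki, rel=0.005)

    def test_too_few_late_frames_rejected(self, input_fn):
        sched = FrameSchedule.from_durations([300.0, 300.0])  # ends at 10 min
        tac = TimeActivityCurve(schedule=sched, activity=[1.0, 1.0])
        with pytest.raises(ValueError, match="frames"):
            fk.patlak_fit(tac, input_fn)

    def test_zero_plasma_activity_rejected(self, schedule):
        t = np.arange(0.0, 4501.0)
        inp = fk.InputFunction(time=t, activity=np.zeros_like(t))
        tac = TimeActivityCurve(schedule=schedule, activity=np.ones(32))
        with pytest.raises(ValueError, match="plasma"):
            fk.patlak_fit(tac, inp)


class TestSokoloffFit:
    def test_recovers_generating_parameters(self, schedule, input_fn):
        p = fk.table1_params("LPS-Lav-", "sokoloff")
        tac, _ = fk.simulate(p, input_fn, schedule, step=0.1)
        res = fk.fit_sokoloff(tac, input_fn, n_starts=32, seed=1)
        assert res.converged
        for name in ("fb", "k1", "k2", "k3"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(p, name), rel=0.02), name

    def test_zero_tac_fits_zero_uptake(self, schedule, input_fn):
        tac = TimeActivityCurve(schedule=schedule, activity=np.zeros(32))
        res = fk.fit_sokoloff(tac, input_fn, n_starts=8, seed=0)
        q = res.params
        ki = q.k1 * q.k3 / (q.k2 + q.k3) if q.k2 + q.k3 > 0 else 0.0
        assert ki < 1e-6
        assert q.k1 < 1e-3  # near the lower bound (0.02% of the search box)

    def test_overestimates_ki_when_extra_cellular_pool_present(self, schedule,
                                                               input_fn):
        base = fk.table1_params("LPS+Lav+", "fourcomp")
        truth = fk.models.with_params(base, k5=0.04, k6=0.06)
        tac, _ = fk.simulate(truth, input_fn, schedule, step=0.1)
        res = fk.fit_sokoloff(tac, input_fn, n_starts=16, seed=3)
        ki_s = fk.ki_irreversible(res.params.k1, res.params.k2, res.params.k3)
        ki_f = fk.ki_irreversible(truth.k1, truth.k2, truth.k3)
        assert ki_s > ki_f

    def test_amplitude_invariance(self, schedule):
        p = fk.table1_params("LPS-Lav-", "sokoloff")
        small = fk.make_input_function(amplitude=1.0)
        large = fk.make_input_function(amplitude=250.0)
        tac_s, _ = fk.simulate(p, small, schedule, step=0.1)
        tac_l, _ = fk.simulate(p, large, schedule, step=0.1)
        ra = fk.fit_sokoloff(tac_s, small, n_starts=8, seed=5)
        rb = fk.fit_sokoloff(tac_l, large, n_starts=8, seed=5)
        for name in ("fb", "k1", "k2", "k3"):
            assert getattr(ra.params, name) == pytest.approx(
                getattr(rb.params, name), rel=1e-4, abs=1e-10), name

    def test_more_starts_never_increase_best_sse(self, schedule, input_fn):
        base = fk.table1_params("LPS+Lav+", "fourcomp")
        tac, _ = fk.simulate(base, input_fn, schedule, step=0.5)
        sses = [fk.fit_sokoloff(tac, input_fn, n_starts=n, seed=11).sse
                for n in (2, 4, 8, 16)]
        assert all(b <= a + 1e-18 for a, b in zip(sses, sses[1:]))

    def test_deterministic_under_fixed_seed(self, schedule, input_fn):
        p = fk.table1_params("LPS+Lav+", "sokoloff")
        tac, _ = fk.simulate(p, input_fn, schedule, step=0.5)
        a = fk.fit_sokoloff(tac, input_fn, n_starts=8, seed=7)
        b = fk.fit_sokoloff(tac, input_fn, n_starts=8, seed=7)
        assert a.params == b.params and a.sse == b.sse


class TestFourCompFit:
    def test_recovers_generating_parameters(self, schedule, input_fn):
        p = fk.table1_params("LPS-Lav-", "fourcomp")
        tac, _ = fk.simulate(p, input_fn, schedule, step=0.1)
        res = fk.fit_fourcomp(tac, input_fn, n_starts=32, seed=1)
        assert res.converged
        q = res.params
        ki_t = fk.ki_irreversible(p.k1, p.k2, p.k3)
        ki_e = fk.ki_irreversible(q.k1, q.k2, q.k3)
        assert ki_e == pytest.approx(ki_t, rel=0.02)
        assert fk.fe_fraction(q.k1, q.k2, q.k3) == pytest.approx(
            fk.fe_fraction(p.k1, p.k2, p.k3), rel=0.10)
        assert fk.fee_fraction(q) == pytest.approx(fk.fee_fraction(p), rel=0.10)

    def test_nested_fit_of_sokoloff_data_recovers_ki(self, schedule, input_fn):
        p = fk.table1_params("LPS+Lav+", "sokoloff")
        tac, _ = fk.simulate(p, input_fn, schedule, step=0.1)
        res = fk.fit_fourcomp(tac, input_fn, n_starts=16, seed=2)
        ki_e = fk.ki_irreversible(res.params.k1, res.params.k2, res.params.k3)
        assert ki_e == pytest.approx(fk.ki_irreversible(p.k1, p.k2, p.k3),
                                     rel=0.02)

    def test_zero_tac_fits_zero_uptake(self, schedule, input_fn):
        tac = TimeActivityCurve(schedule=schedule, activity=np.zeros(32))
        res = fk.fit_fourcomp(tac, input_fn, n_starts=8, seed=0)
        q = res.params
        ki = q.k1 * q.k3 / (q.k2 + q.k3) if q.k2 + q.k3 > 0 else 0.0
        assert ki < 1e-6
        assert q.k1 < 1e-3  # near the lower bound (0.02% of the search box)


class TestAic:
    def test_parameter_penalty_arithmetic(self):
        assert fk.aic(1.0, 32, 6) - fk.aic(1.0, 32, 4) == pytest.approx(4.0)

    def test_halved_sse_closed_form(self):
        assert fk.aic(0.5, 32, 4) - fk.aic(1.0, 32, 4) == pytest.approx(
            -32 * math.log(2))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="sse"):
            fk.aic(0.0, 32, 4)
        with pytest.raises(ValueError, match="n_frames"):
            fk.aic(1.0, 4, 4)

    def test_fourcomp_wins_on_data_with_substantial_fee(self, schedule, input_fn):
        truth = fk.table1_params("LPS+Lav+", "fourcomp")
        tac, _ = fk.simulate(truth, input_fn, schedule, step=0.1)
        sok = fk.fit_sokoloff(tac, input_fn, n_starts=16, seed=4)
        fc = fk.fit_fourcomp(tac, input_fn, n_starts=16, seed=4)
        assert fc.aic < sok.aic
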