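"""Tests of the four-step ABR/CPR controller."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zeroflow as zf
from zeroflow.reflex_control import (
    ControllerNotWarmed,
    ReflexConfigError,
    ReflexController,
    TriangularArc,
    apply_gains,
    convolve_arc,
    error_signal,
    integrate_afferent,
    make_kernel,
    saturate,
)
from zeroflow.scenarios import ScenarioConfig
from zeroflow.cv_model import simulate


# ---------------------------------------------------------------------------
# Step I: afferent smoothing
# ---------------------------------------------------------------------------

class TestAfferent:
    def test_mean_of_constant(self):
        assert integrate_afferent([95.0] * 250, 250) == pytest.approx(95.0)

    def test_alternating_symmetry(self):
        buf = [90.0, 100.0] * 125
        assert integrate_afferent(buf, 250) == pytest.approx(95.0)

    def test_ramp_mean_closed_form(self):
        # mean of 0..249 = 249/2 = 124.5
        assert integrate_afferent(np.arange(250.0), 250) == pytest.approx(124.5)

    def test_warmup_pads_with_first_sample(self):
        # 10 samples of 80 padded to 250 -> still 80
        assert integrate_afferent([80.0] * 10, 250) == pytest.approx(80.0)

    def test_empty_buffer_raises(self):
        with pytest.raises(ControllerNotWarmed):
            integrate_afferent([], 250)


def test_error_signal_is_plain_offset():
    assert error_signal(95.0, 95.0) == 0.0
    assert error_signal(3.0, 3.0) == 0.0
    assert error_signal(110.0, 95.0) == 15.0


# ---------------------------------------------------------------------------
# Step II: arctan saturation
# ---------------------------------------------------------------------------

class TestSaturation:
    def test_odd_at_zero(self):
        assert saturate(0.0, 18.0) == 0.0

    def test_asymptote_never_exceeded(self):
        assert saturate(1e12, 18.0) < 18.0
        assert saturate(-1e12, 18.0) > -18.0

    def test_stated_form_value(self):
        # (2L/pi) atan(pi e / 2L) at e = L = 5
        assert saturate(5.0, 5.0) == pytest.approx((10 / np.pi) * np.arctan(np.pi / 2))
        assert saturate(5.0, 5.0) == pytest.approx(3.20, abs=0.01)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(e=st.floats(-1e9, 1e9), L=st.sampled_from([5.0, 18.0]))
    def test_bounded_odd_and_monotone(self, e, L):
        y = saturate(e, L)
        assert abs(y) < L
        assert y == pytest.approx(-saturate(-e, L), abs=1e-12)

    def test_unit_slope_at_origin(self):
        assert saturate(1e-4, 18.0) == pytest.approx(1e-4, rel=1e-6)


# ---------------------------------------------------------------------------
# Step III: unit-area kernels and convolution
# ---------------------------------------------------------------------------

class TestKernels:
    def test_unit_area_after_discretization(self):
        for d, p, e in [(0.2, 0.7, 1.2), (2.0, 40.0, 200.0), (30.0, 180.0, 450.0)]:
            k = make_kernel(d, p, e, fs=200.0)
            assert k.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bad_breakpoints_rejected(self):
        with pytest.raises(ReflexConfigError):
            make_kernel(1.0, 1.0, 2.0, fs=200.0)

    def test_constant_input_reproduced_after_support(self):
        k = make_kernel(0.1, 0.3, 0.8, fs=200.0)
        out = convolve_arc(np.full(400, 2.0), k)
        assert out[-1] == pytest.approx(2.0, abs=1e-9)

    def test_impulse_returns_kernel(self):
        k = make_kernel(0.1, 0.3, 0.8, fs=200.0)
        x = np.zeros(len(k))
        x[0] = 1.0
        assert np.allclose(convolve_arc(x, k), k)

    def test_step_response_matches_cumulative_kernel(self):
        k = make_kernel(0.1, 0.3, 0.6, fs=200.0)
        step_in = np.ones(len(k) + 50)
        out = convolve_arc(step_in, k)
        expect = np.cumsum(np.concatenate([k, np.zeros(50)]))
        assert np.max(np.abs(out - expect)) < 1e-9

    def test_non_unit_kernel_rejected(self):
        with pytest.raises(ReflexConfigError, match="area"):
            convolve_arc(np.ones(10), np.ones(5))

    def test_recursive_arc_matches_direct_convolution(self):
        rng = np.random.default_rng(0)
        arc = TriangularArc("a", "arterial", "abr", 0.05, 0.2, 0.5, fs=200.0)
        arc.warm_start(0.0)
        x = rng.normal(size=600)
        ys = np.array([arc.push(v) for v in x])
        direct = np.convolve(x, arc.weights)[: len(x)]
        assert np.max(np.abs(ys - direct)) < 1e-9

    def test_warm_start_is_steady_state(self):
        arc = TriangularArc("a", "arterial", "abr", 0.1, 0.5, 2.0, fs=200.0)
        arc.warm_start(3.7)
        for _ in range(100):
            assert arc.push(3.7) == pytest.approx(3.7, abs=1e-12)


# ---------------------------------------------------------------------------
# Step IV: gains
# ---------------------------------------------------------------------------

GAINS = {
    "heart_rate": {"s": -0.5},
    "contractility": {"s": -0.01},
    "peripheral_resistance": {"s": -0.02},
    "unstressed_volume": {"s": 30.0},
}
BASE = {"heart_rate": 75.0, "contractility": 1.0,
        "peripheral_resistance": 1.0, "unstressed_volume": 0.0}


class TestGains:
    def test_zero_efferents_give_base(self):
        out = apply_gains({"s": 0.0}, GAINS, BASE)
        assert out == BASE

    def test_hypotension_constricts_and_recruits_volume(self):
        out = apply_gains({"s": -10.0}, GAINS, BASE)  # pressure below set point
        assert out["peripheral_resistance"] > 1.0
        assert out["unstressed_volume"] < 0.0
        assert out["heart_rate"] > 75.0

    def test_linearity_in_gain(self):
        double = {k: {a: 2 * g for a, g in v.items()} for k, v in GAINS.items()}
        one = apply_gains({"s": -4.0}, GAINS, BASE)
        two = apply_gains({"s": -4.0}, double, BASE)
        assert (two["heart_rate"] - 75.0) == pytest.approx(
            2 * (one["heart_rate"] - 75.0))

    def test_physiological_floors(self):
        out = apply_gains({"s": 1e6}, GAINS, BASE)
        assert out["heart_rate"] == 0.0
        assert out["peripheral_resistance"] == 0.1


# ---------------------------------------------------------------------------
# closed-loop controller
# ---------------------------------------------------------------------------

class TestController:
    def _controller(self, topo):
        return ReflexController(topo.reflex, topo.n, topo.heart_rate)

    def test_tick_before_warm_start_raises(self, human_topo):
        ctrl = self._controller(human_topo)
        with pytest.raises(ControllerNotWarmed):
            ctrl.tick(95.0, 3.0)

    def test_fixed_point_at_setpoints(self, human_topo):
        ctrl = self._controller(human_topo)
        sp = ctrl.setpoints
        ctrl.warm_start(sp.arterial_pressure, sp.venous_pressure)
        # hold a pulse whose window max-min equals the pulse-pressure set point
        half = sp.pulse_pressure / 2.0
        for k in range(1000):
            p = sp.arterial_pressure + half * np.sign(np.sin(2 * np.pi * k / 100))
            hr, esc, rsc, dv0 = ctrl.tick(p, sp.venous_pressure)
        assert hr == pytest.approx(human_topo.heart_rate, abs=1.5)
        assert esc == pytest.approx(1.0, abs=0.02)
        assert rsc == pytest.approx(1.0, abs=0.05)
        assert np.abs(dv0).sum() < 30.0

    def test_hypotension_raises_hr_and_resistance(self, human_topo):
        ctrl = self._controller(human_topo)
        ctrl.warm_start(95.0, 3.0)
        for _ in range(int(40 * ctrl.fs)):  # beyond the slow-kernel delay
            hr, esc, rsc, dv0 = ctrl.tick(55.0, 3.0)  # sudden arterial drop
        assert hr > human_topo.heart_rate
        assert rsc > 1.0
        assert dv0.sum() < 0.0  # venoconstriction recruits stressed volume

    def test_disabled_controller_pins_base(self, human_topo):
        ctrl = ReflexController(human_topo.reflex, human_topo.n,
                                human_topo.heart_rate, enabled=False)
        ctrl.warm_start(60.0, 10.0)
        for _ in range(300):
            hr, esc, rsc, dv0 = ctrl.tick(40.0, 12.0)
        assert (hr, esc, rsc) == (human_topo.heart_rate, 1.0, 1.0)
        assert np.all(dv0 == 0.0)


class TestReflexOffEquivalence:
    def test_zero_gains_bit_identical_to_no_controller(self, human_topo):
        """With every gain zeroed the controller must be a perfect no-op."""
        import copy

        reflex = copy.deepcopy(human_topo.reflex)
        for eff in reflex["gains"]:
            reflex["gains"][eff] = {a: 0.0 for a in reflex["gains"][eff]}
        ctrl = ReflexController(reflex, human_topo.n, human_topo.heart_rate)
        sc = ScenarioConfig("euvolemia", True, baseline_duration=8.0,
                            trace_keep=8.0, horizon_post_arrest=600.0,
                            steady_tolerance=50.0)
        with_ctrl = simulate(human_topo, sc, ctrl)
        without = simulate(human_topo, sc, None)
        assert np.array_equal(with_ctrl.abp, without.abp)
        assert np.array_equal(with_ctrl.cvp, without.cvp)
        assert np.array_equal(with_ctrl.co, without.co)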