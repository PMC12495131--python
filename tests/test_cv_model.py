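"""Unit and property tests of the lumped-parameter network."""

from __future__ import annotations

import copy

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import zeroflow as zf
from zeroflow.cv_model import (
    ABDOMINAL_AORTA,
    CompartmentSpec,
    Edge,
    ModelConfigError,
    ModelTopology,
    build_model,
    cardiac_elastance,
    compartment_pressure,
    flows,
    load_model_config,
    step,
)


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------

class TestBuild:
    def test_default_model_structure(self, human_topo):
        assert human_topo.n == 21
        assert human_topo.compartments[0].kind == "arterial"
        assert human_topo.compartments[15].is_cardiac
        assert human_topo._strongly_connected()

    def test_initial_volumes_sum_to_total(self, human_topo):
        state = human_topo.initial_state()
        assert state.total_volume() == pytest.approx(
            human_topo.total_blood_volume, rel=1e-12)

    def test_initial_volumes_follow_requested_total(self, human_topo):
        state = human_topo.initial_state(5000.0)
        assert state.total_volume() == pytest.approx(5000.0, rel=1e-12)

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda c: c["compartments"][3].__setitem__("C", 0.0), "compliance"),
            (lambda c: c["compartments"].pop(5), "indexed"),
            (lambda c: c["connections"][0].__setitem__("R", -1.0), "R must be"),
            (lambda c: c["compartments"][15].__setitem__("E_min", 2.0), "E_max >= E_min"),
        ],
    )
    def test_invalid_configs_rejected(self, mutate, match):
        cfg = copy.deepcopy(load_model_config("human_default"))
        mutate(cfg)
        with pytest.raises(ModelConfigError, match=match):
            build_model(cfg)

    def test_disconnected_topology_rejected(self):
        cfg = copy.deepcopy(load_model_config("human_default"))
        # cut the loop: remove the aortic-valve edge
        cfg["connections"] = [e for e in cfg["connections"]
                              if not (e["from"] == 20 and e["to"] == 0)]
        with pytest.raises(ModelConfigError, match="strongly connected"):
            build_model(cfg)


# ---------------------------------------------------------------------------
# elementary laws
# ---------------------------------------------------------------------------

def _passive(C=2.0, v0=100.0):
    return CompartmentSpec(0, "x", "venous", V_unstressed=v0, C=C)


def _cardiac(emin=0.1, emax=2.0, v0=20.0):
    return CompartmentSpec(20, "lv", "cardiac", V_unstressed=v0,
                           E_min=emin, E_max=emax)


class TestPressureLaw:
    def test_zero_stressed_volume(self):
        assert compartment_pressure(_passive(), V=100.0) == 0.0

    def test_linear_law(self):
        assert compartment_pressure(_passive(C=2.0), V=150.0) == pytest.approx(25.0)

    def test_cardiac_with_external_pressure(self):
        spec = _cardiac(v0=20.0)
        p = compartment_pressure(spec, V=140.0, E_now=0.1, P_ext=-4.0)
        assert p == pytest.approx(8.0)

    def test_pressure_below_external_permitted(self):
        assert compartment_pressure(_passive(), V=50.0, P_ext=0.0) < 0.0


class TestElastance:
    def test_diastole_returns_emin(self):
        assert cardiac_elastance(_cardiac(), 0.95) == pytest.approx(0.1)

    def test_systolic_peak_returns_emax(self):
        # ventricular activation peaks mid-systole
        T = 0.8
        dur = 0.3 * np.sqrt(T) / T
        peak_phase = 0.15 + dur / 2
        assert cardiac_elastance(_cardiac(), peak_phase, cycle_length=T) == \
            pytest.approx(2.0, rel=1e-6)

    def test_arrest_floor(self):
        assert cardiac_elastance(_cardiac(emin=0.1), 0.3, arrest=True) == 0.1
        assert cardiac_elastance(_cardiac(emin=0.0), 0.3, arrest=True) == 1e-3

    def test_non_cardiac_rejected(self):
        with pytest.raises(ValueError):
            cardiac_elastance(_passive(), 0.5)


class TestFlows:
    def test_no_gradient_no_flow(self, human_topo):
        p = np.full(human_topo.n, 10.0)
        assert np.all(flows(human_topo, p) == 0.0)

    def test_ohm_analogy_and_diode(self):
        comps = (
            CompartmentSpec(0, "a", "arterial", 10.0, C=1.0),
            CompartmentSpec(1, "b", "venous", 10.0, C=1.0),
        )
        edges = (Edge(0, 1, R=1.0), Edge(1, 0, R=1.0, valved=True))
        topo = ModelTopology(comps, edges, total_blood_volume=100.0)
        q = flows(topo, np.array([20.0, 10.0]))
        assert q[0] == pytest.approx(10.0)   # 10 mmHg over 1 PRU
        assert q[1] == 0.0                   # diode blocks retrograde


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class TestStep:
    def test_equilibrium_is_fixed_point(self, human_topo):
        state = human_topo.initial_state()
        state.arrested = True
        state.HR = 0.0
        out = step(human_topo, state, dt=0.01)
        assert np.allclose(out.V, state.V, atol=1e-9)

    def test_volume_conserved_over_beats(self, human_topo):
        state = human_topo.initial_state()
        total0 = state.total_volume()
        for _ in range(2000):  # 2 s of beating at 1 ms
            state = step(human_topo, state, 1e-3, P_intrathoracic=-4.0)
        assert abs(state.total_volume() - total0) < 1e-6 * total0

    def test_nan_detection_aborts(self, human_topo):
        state = human_topo.initial_state()
        state.V[:] = np.nan
        with pytest.raises(zf.cv_model.SimulationError):
            step(human_topo, state, 1e-3)


def _toy_loop():
    """3-compartment closed loop with one diode-free cycle."""
    comps = (
        CompartmentSpec(0, "a", "arterial", 50.0, C=1.5),
        CompartmentSpec(1, "b", "venous", 200.0, C=20.0),
        CompartmentSpec(2, "c", "venous", 100.0, C=5.0),
    )
    edges = (Edge(0, 1, R=1.0), Edge(1, 2, R=0.5), Edge(2, 0, R=0.2))
    return ModelTopology(comps, edges, total_blood_volume=600.0,
                         right_atrium_index=0, aortic_arch_index=0)


class TestAgainstIndependentIntegrator:
    """Small-instance oracle: the fixed-step solver must agree with an
    independently formulated dense-output stiff ODE solution."""

    def test_toy_loop_matches_lsoda(self):
        topo = _toy_loop()
        C = np.array([1.5, 20.0, 5.0])
        v0 = np.array([50.0, 200.0, 100.0])
        R = np.array([1.0, 0.5, 0.2])
        src = np.array([0, 1, 2])
        dst = np.array([1, 2, 0])

        def rhs(t, V):
            p = (V - v0) / C
            q = (p[src] - p[dst]) / R
            dV = np.zeros(3)
            np.subtract.at(dV, src, q)
            np.add.at(dV, dst, q)
            return dV

        V_init = v0 + np.array([200.0, 30.0, 20.0])  # off-equilibrium start
        ref = solve_ivp(rhs, (0, 20.0), V_init, method="LSODA",
                        rtol=1e-10, atol=1e-10, dense_output=True)

        state = zf.ModelState(t=0.0, V=V_init.copy(), cardiac_phase=0.0,
                              resp_phase=0.0, HR=0.0, RR=0.0, arrested=True)
        dt = 1e-3
        for k in range(int(20.0 / dt)):
            state = step(topo, state, dt)
        p_sim = (state.V - v0) / C
        p_ref = (ref.sol(20.0) - v0) / C
        assert np.max(np.abs(p_sim - p_ref)) < 0.1

    def test_dt_halving_converges(self):
        topo = _toy_loop()
        v0 = topo._V0
        V_init = v0 + np.array([200.0, 30.0, 20.0])

        def run(dt):
            state = zf.ModelState(t=0.0, V=V_init.copy(), cardiac_phase=0.0,
                                  resp_phase=0.0, HR=0.0, RR=0.0, arrested=True)
            for _ in range(int(2.0 / dt)):
                state = step(topo, state, dt)
            return state.V

        err1 = np.max(np.abs(run(2e-3) - run(5e-4)))
        err2 = np.max(np.abs(run(1e-3) - run(5e-4)))
        assert err2 < err1  # first-order scheme: halving dt shrinks the error


# ---------------------------------------------------------------------------
# zero-flow equilibrium (MCFP)
# ---------------------------------------------------------------------------

class TestMcfp:
    def test_closed_form_value(self, human_topo):
        # (V_total - sum V0) / sum C_eff with arrested-chamber compliances
        v0 = sum(c.V_unstressed for c in human_topo.compartments)
        ceff = human_topo.effective_compliances().sum()
        expect = (human_topo.total_blood_volume - v0) / ceff
        assert human_topo.mcfp() == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("dv", [1.0, 50.0, 500.0])
    def test_monotone_in_total_volume(self, human_topo, dv):
        base = human_topo.mcfp()
        assert human_topo.mcfp(human_topo.total_blood_volume + dv) > base

    @pytest.mark.parametrize("dv0", [1.0, 50.0, 300.0])
    def test_monotone_in_unstressed_volume(self, human_topo, dv0):
        assert human_topo.mcfp(dv0_total=dv0) < human_topo.mcfp()


# ---------------------------------------------------------------------------
# whole-scenario behavior
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_baseline_is_pulsatile_with_forward_flow(self, eu_off_trace):
        pre = eu_off_trace.t < 0
        abp = eu_off_trace.abp[pre]
        assert eu_off_trace.co[pre].mean() > 2.0  # L/min
        assert abp.max() - abp.min() > 20.0       # pulse pressure

    def test_reflex_off_pressures_equalize(self, eu_off_trace):
        late = eu_off_trace.t > 550
        gap = np.abs(eu_off_trace.abp[late] - eu_off_trace.cvp[late])
        assert gap.max() < 0.5

    def test_trace_is_uniform_and_spans_window(self, eu_off_trace):
        assert eu_off_trace.fs == 200.0
        assert eu_off_trace.t[0] <= -20.0
        assert eu_off_trace.t[-1] >= 600.0
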