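"""Closed-loop 21-compartment lumped-parameter cardiovascular model.

The circulation is represented as a closed loop of two-element Windkessel
compartments (an inflow/outflow resistance plus a compliance), following the
CVSim-21 model family: pressure is the voltage at each node, flow the current
through each resistor, and blood volume the charge stored on each capacitor.
Four cardiac chambers are time-varying elastance elements driven by heart
rate; thoracic compartments feel a common intrathoracic pressure waveform.

Volumes are the state variables, ``dV_i/dt = sum(Q_in) - sum(Q_out)``.  The
network is integrated with a fixed-step backward-Euler scheme (the system is
piecewise linear in V, so each step is one 21x21 solve), which is
unconditionally stable, conserves total volume to solver round-off, and
relaxes to the exact zero-flow equilibrium of the linear network - the
model's mean circulatory filling pressure (MCFP).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CompartmentSpec",
    "Edge",
    "ModelTopology",
    "ModelState",
    "HemoTrace",
    "ModelConfigError",
    "SimulationError",
    "build_default_model",
    "build_model",
    "load_model_config",
    "compartment_pressure",
    "cardiac_elastance",
    "flows",
    "step",
    "simulate",
    "mean_circulatory_filling_pressure",
]

AORTIC_ARCH = 0
ABDOMINAL_AORTA = 6
RIGHT_ATRIUM = 15
RIGHT_VENTRICLE = 16
PULMONARY_ARTERY = 17

# ventricular chambers receive the contractility effector
_VENTRICLES = (16, 20)
# cardiac activation timing (fractions of the cycle; ventricular systolic
# duration scales with sqrt(cycle length), a standard elastance convention)
_ATRIAL_ONSET = 0.0
_ATRIAL_DURATION = 0.20
_VENTRICULAR_ONSET = 0.15
_VENTRICULAR_SYSTOLE_COEFF = 0.30  # duration = 0.30 * sqrt(T) seconds


class ModelConfigError(ValueError):
    """Raised when a model configuration violates a structural invariant."""


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-physical state."""


@dataclass(frozen=True)
class CompartmentSpec:
    """Static parameters of one vascular or cardiac compartment."""

    index: int
    name: str
    kind: str  # arterial | venous | cardiac | pulmonary
    V_unstressed: float
    C: float | None = None
    E_min: float | None = None
    E_max: float | None = None
    thoracic: bool = False

    @property
    def is_cardiac(self) -> bool:
        return self.kind == "cardiac"

    def validate(self) -> None:
        if self.kind not in ("arterial", "venous", "cardiac", "pulmonary"):
            raise ModelConfigError(
                f"compartment {self.index} ({self.name}): unknown kind {self.kind!r}"
            )
        if self.V_unstressed < 0:
            raise ModelConfigError(
                f"compartment {self.index} ({self.name}): V_unstressed must be >= 0"
            )
        if self.is_cardiac:
            if self.E_min is None or self.E_max is None:
                raise ModelConfigError(
                    f"compartment {self.index} ({self.name}): cardiac compartment "
                    "requires E_min and E_max"
                )
            if not (self.E_max >= self.E_min >= 0):
                raise ModelConfigError(
                    f"compartment {self.index} ({self.name}): requires E_max >= E_min >= 0"
                )
        else:
            if self.C is None or self.C <= 0:
                raise ModelConfigError(
                    f"compartment {self.index} ({self.name}): compliance C must be > 0"
                )


@dataclass(frozen=True)
class Edge:
    """Directed resistive connection between two compartments."""

    src: int
    dst: int
    R: float
    valved: bool = False
    microcirculation: bool = False


@dataclass(frozen=True)
class ModelTopology:
    """Validated closed-loop network plus global simulation settings."""

    compartments: tuple[CompartmentSpec, ...]
    edges: tuple[Edge, ...]
    total_blood_volume: float
    epsilon_elastance: float = 1e-3
    dt: float = 1e-3
    dt_post_arrest: float = 5e-3
    fs: float = 200.0
    heart_rate: float = 75.0
    respiratory_rate: float = 12.0
    intrathoracic_pressure: float = -4.0
    respiratory_amplitude: float = 2.5
    rectify_microcirculation: bool = True
    arrest_valve_r_factor: float = 200.0
    arrest_tone_valve_gain: float = 300.0
    ignore_valves: bool = False
    name: str = "model"
    aortic_arch_index: int = AORTIC_ARCH
    right_atrium_index: int = RIGHT_ATRIUM
    reflex: dict = field(default_factory=dict, compare=False)

    # --- derived arrays -------------------------------------------------
    def __post_init__(self):
        n = len(self.compartments)
        cardiac = np.array([c.is_cardiac for c in self.compartments])
        C = np.array([c.C if c.C is not None else np.nan for c in self.compartments])
        emin = np.array([c.E_min if c.E_min is not None else np.nan for c in self.compartments])
        emax = np.array([c.E_max if c.E_max is not None else np.nan for c in self.compartments])
        v0 = np.array([c.V_unstressed for c in self.compartments], dtype=float)
        thor = np.array([c.thoracic for c in self.compartments])
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "_cardiac", cardiac)
        object.__setattr__(self, "_C", C)
        object.__setattr__(self, "_Emin", emin)
        object.__setattr__(self, "_Emax", emax)
        object.__setattr__(self, "_V0", v0)
        object.__setattr__(self, "_thoracic", thor)
        object.__setattr__(self, "_src", np.array([e.src for e in self.edges]))
        object.__setattr__(self, "_dst", np.array([e.dst for e in self.edges]))
        object.__setattr__(self, "_R", np.array([e.R for e in self.edges], dtype=float))
        valved = np.array([e.valved for e in self.edges])
        oneway = np.array(
            [e.valved or (e.microcirculation and self.rectify_microcirculation)
             for e in self.edges]
        )
        if self.ignore_valves:
            oneway[:] = False
        object.__setattr__(self, "_valved", valved)
        object.__setattr__(self, "_oneway", oneway)
        object.__setattr__(self, "_micro", np.array([e.microcirculation for e in self.edges]))

    # --- validation -----------------------------------------------------
    def validate(self) -> "ModelTopology":
        ids = [c.index for c in self.compartments]
        if ids != list(range(len(ids))):
            missing = sorted(set(range(max(ids, default=0) + 1)) - set(ids))
            raise ModelConfigError(f"compartments must be indexed 0..n-1; missing {missing}")
        for c in self.compartments:
            c.validate()
        for e in self.edges:
            if e.R <= 0:
                raise ModelConfigError(f"connection {e.src}->{e.dst}: R must be > 0")
            if not (0 <= e.src < self.n and 0 <= e.dst < self.n):
                raise ModelConfigError(f"connection {e.src}->{e.dst}: unknown compartment")
        if self.total_blood_volume <= 0:
            raise ModelConfigError("total_blood_volume must be > 0")
        if not self._strongly_connected():
            raise ModelConfigError("connections do not form a strongly connected closed loop")
        if not self.compartments[self.aortic_arch_index].kind == "arterial":
            raise ModelConfigError("aortic_arch_index must point at an arterial compartment")
        if not self.compartments[self.right_atrium_index].is_cardiac:
            raise ModelConfigError("right_atrium_index must point at a cardiac compartment")
        return self

    def _strongly_connected(self) -> bool:
        def reach(adj):
            seen = {0}
            stack = [0]
            while stack:
                for j in adj.get(stack.pop(), ()):
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            return len(seen) == self.n

        fwd: dict[int, list[int]] = {}
        rev: dict[int, list[int]] = {}
        for e in self.edges:
            fwd.setdefault(e.src, []).append(e.dst)
            rev.setdefault(e.dst, []).append(e.src)
        return reach(fwd) and reach(rev)

    # --- derived quantities ---------------------------------------------
    def arrest_elastances(self) -> np.ndarray:
        """Elastance of each cardiac chamber after arrest (activation off).

        Chambers relax to their diastolic elastance ``E_min``, floored at
        ``epsilon_elastance`` so a chamber can never become an infinite
        reservoir.
        """
        return np.maximum(self._Emin[self._cardiac], self.epsilon_elastance)

    def effective_compliances(self) -> np.ndarray:
        """Per-compartment compliance of the arrested (passive) network."""
        c = self._C.copy()
        c[self._cardiac] = 1.0 / self.arrest_elastances()
        return c

    def mcfp(self, total_volume: float | None = None, dv0_total: float = 0.0) -> float:
        """Closed-form zero-flow equilibrium pressure of the arrested network.

        With all external pressures zero the linear network relaxes to the
        single pressure ``(V_total - sum V0) / sum C_eff`` - the model's mean
        circulatory filling pressure.  ``dv0_total`` shifts the summed
        unstressed volume (the venous-tone effector).
        """
        v = self.total_blood_volume if total_volume is None else total_volume
        stressed = v - (self._V0.sum() + dv0_total)
        return stressed / self.effective_compliances().sum()

    def initial_state(self, total_volume: float | None = None) -> "ModelState":
        """Equilibrium starting state: stressed volume distributed over the
        effective compliances so every compartment starts at the same
        pressure (the MCFP of the requested volume)."""
        v = self.total_blood_volume if total_volume is None else total_volume
        ceff = self.effective_compliances()
        stressed = v - self._V0.sum()
        V = self._V0 + stressed * ceff / ceff.sum()
        return ModelState(
            t=0.0, V=V, cardiac_phase=0.0, resp_phase=0.0,
            HR=self.heart_rate, RR=self.respiratory_rate, arrested=False,
        )


@dataclass
class ModelState:
    """Instantaneous state of the circulation."""

    t: float
    V: np.ndarray
    cardiac_phase: float
    resp_phase: float
    HR: float
    RR: float
    arrested: bool = False

    def copy(self) -> "ModelState":
        return dataclasses.replace(self, V=self.V.copy())

    def total_volume(self) -> float:
        return float(self.V.sum())


@dataclass
class HemoTrace:
    """Uniformly sampled ABP/CVP/CO recording, arrest at t = 0."""

    fs: float
    t: np.ndarray
    abp: np.ndarray
    cvp: np.ndarray
    co: np.ndarray
    label: str = ""

    def __post_init__(self):
        lens = {len(self.t), len(self.abp), len(self.cvp), len(self.co)}
        if len(lens) != 1:
            raise ValueError("all channels must have the same length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValueError("trace is not uniformly sampled at fs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "abp_mmhg": self.abp,
                "cvp_mmhg": self.cvp,
                "co_l_min": self.co,
                "label": self.label,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "HemoTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        label = str(df["label"].iloc[0]) if "label" in df and len(df) else ""
        return cls(
            fs=fs, t=t,
            abp=df["abp_mmhg"].to_numpy(float),
            cvp=df["cvp_mmhg"].to_numpy(float),
            co=df["co_l_min"].to_numpy(float),
            label=label,
        )

    def channel(self, name: str) -> np.ndarray:
        return {"abp": self.abp, "map": self.abp, "cvp": self.cvp, "co": self.co}[name]


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def load_model_config(name_or_path: str = "human_default") -> dict:
    """Load a model configuration, either packaged (by name) or from a path."""
    packaged = {"human_default", "pig_calibrated"}
    if name_or_path in packaged:
        text = resources.files("zeroflow.config").joinpath(f"{name_or_path}.yaml").read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def build_model(config: dict) -> ModelTopology:
    """Build and validate a :class:`ModelTopology` from a config mapping."""
    try:
        comp_rows = config["compartments"]
        conn_rows = config["connections"]
    except KeyError as exc:
        raise ModelConfigError(f"config missing required block: {exc}") from exc
    comps = tuple(
        CompartmentSpec(
            index=int(r["id"]),
            name=str(r["name"]),
            kind=str(r["kind"]),
            V_unstressed=float(r["V0"]),
            C=float(r["C"]) if "C" in r else None,
            E_min=float(r["E_min"]) if "E_min" in r else None,
            E_max=float(r["E_max"]) if "E_max" in r else None,
            thoracic=bool(r.get("thoracic", False)),
        )
        for r in sorted(comp_rows, key=lambda r: int(r["id"]))
    )
    edges = tuple(
        Edge(
            src=int(r["from"]), dst=int(r["to"]), R=float(r["R"]),
            valved=bool(r.get("valved", False)),
            microcirculation=bool(r.get("microcirculation", False)),
        )
        for r in conn_rows
    )
    topo = ModelTopology(
        compartments=comps,
        edges=edges,
        total_blood_volume=float(config["total_blood_volume_ml"]),
        epsilon_elastance=float(config.get("epsilon_elastance", 1e-3)),
        dt=float(config.get("dt_s", 1e-3)),
        dt_post_arrest=float(config.get("dt_post_arrest_s", 5e-3)),
        fs=float(config.get("fs_hz", 200.0)),
        heart_rate=float(config.get("heart_rate_bpm", 75.0)),
        respiratory_rate=float(config.get("respiratory_rate_bpm", 12.0)),
        intrathoracic_pressure=float(config.get("intrathoracic_pressure_mmhg", -4.0)),
        respiratory_amplitude=float(config.get("respiratory_amplitude_mmhg", 2.5)),
        rectify_microcirculation=bool(config.get("rectify_microcirculation", True)),
        arrest_valve_r_factor=float(config.get("arrest_valve_r_factor", 200.0)),
        arrest_tone_valve_gain=float(config.get("arrest_tone_valve_gain", 300.0)),
        ignore_valves=bool(config.get("ignore_valves", False)),
        name=str(config.get("name", "model")),
        reflex=dict(config.get("reflex", {})),
    )
    return topo.validate()


def build_default_model(config: dict | str | None = None) -> ModelTopology:
    """Build the packaged default model (or any named/explicit config)."""
    if config is None:
        config = load_model_config("human_default")
    elif isinstance(config, str):
        config = load_model_config(config)
    return build_model(config)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def compartment_pressure(
    spec: CompartmentSpec, V: float, E_now: float | None = None, P_ext: float = 0.0
) -> float:
    """Pressure of one compartment: linear elastic law plus external pressure."""
    if spec.is_cardiac:
        if E_now is None:
            raise ValueError("cardiac compartment requires the instantaneous elastance")
        return E_now * (V - spec.V_unstressed) + P_ext
    return (V - spec.V_unstressed) / spec.C + P_ext


def _activation(phase: float, onset: float, duration: float) -> float:
    """Raised-half-sine activation: 0 outside systole, peaking mid-systole."""
    x = (phase - onset) % 1.0
    if x < duration:
        return math.sin(math.pi * x / duration)
    return 0.0


def cardiac_elastance(
    spec: CompartmentSpec,
    cardiac_phase: float,
    arrest: bool = False,
    cycle_length: float = 0.8,
    contractility_scale: float = 1.0,
    epsilon_elastance: float = 1e-3,
) -> float:
    """Instantaneous elastance of a cardiac chamber.

    The chamber alternates between ``E_min`` (diastole) and ``E_max``
    (mid-systole) through a raised-half-sine activation; atria lead the
    ventricles, whose systolic duration scales with the square root of the
    cycle length.  During arrest the activation is switched off and the
    chamber holds its diastolic elastance (floored at ``epsilon_elastance``).
    """
    if not spec.is_cardiac:
        raise ValueError(f"compartment {spec.index} ({spec.name}) is not cardiac")
    if arrest:
        return max(spec.E_min, epsilon_elastance)
    if spec.index in _VENTRICLES:
        dur = min(_VENTRICULAR_SYSTOLE_COEFF * math.sqrt(cycle_length) / cycle_length, 0.45)
        u = _activation(cardiac_phase, _VENTRICULAR_ONSET, dur)
        e_max = spec.E_max * contractility_scale
    else:
        u = _activation(cardiac_phase, _ATRIAL_ONSET, _ATRIAL_DURATION)
        e_max = spec.E_max
    return spec.E_min + (max(e_max, spec.E_min) - spec.E_min) * u


def _elastance_vector(
    topo: ModelTopology, phase: float, arrested: bool, cycle_length: float,
    contractility_scale: float,
) -> np.ndarray:
    """1/C for passive compartments, E(t) for cardiac chambers."""
    a = 1.0 / topo._C
    idx = np.flatnonzero(topo._cardiac)
    if arrested:
        a[idx] = topo.arrest_elastances()
    else:
        for i in idx:
            a[i] = cardiac_elastance(
                topo.compartments[i], phase, False, cycle_length,
                contractility_scale, topo.epsilon_elastance,
            )
    return a


# venoconstriction cannot recruit more than this fraction of a compartment's
# resting unstressed volume
V0_FLOOR_FRACTION = 0.25


def _effective_v0(topo, dv0):
    if dv0 is None:
        return topo._V0
    return np.maximum(topo._V0 + dv0, V0_FLOOR_FRACTION * topo._V0)


def _pressures(topo, V, a, p_it, dv0=None):
    return a * (V - _effective_v0(topo, dv0)) + p_it * topo._thoracic


def _edge_resistances(topo: ModelTopology, r_scale: float, arrested: bool,
                      contractility_scale: float = 1.0) -> np.ndarray:
    R = topo._R.copy()
    R[topo._micro] *= r_scale
    if arrested and not topo.ignore_valves:
        # The arrested heart is no longer a low-resistance conduit: without
        # rhythmic valve opening, trans-cardiac transmission is poor.  With
        # sustained sympathetic drive (contractility effector above base) the
        # ischemic myocardium keeps wall tension and obstructs trans-cardiac
        # flow almost completely; a flaccid (reflex-off) heart stays a weak
        # passive conduit.
        tone = 1.0 + topo.arrest_tone_valve_gain * max(0.0, contractility_scale - 1.0)
        R[topo._valved] *= topo.arrest_valve_r_factor * tone
    return R


def flows(
    topo: ModelTopology, pressures: np.ndarray, r_scale: float = 1.0,
    arrested: bool = False, contractility_scale: float = 1.0,
) -> np.ndarray:
    """Per-edge flow (mL/s): Ohm's law, rectified on one-way edges.

    ``r_scale`` multiplies the microcirculatory resistances (the reflex
    peripheral-resistance effector).
    """
    q = (pressures[topo._src] - pressures[topo._dst]) / _edge_resistances(
        topo, r_scale, arrested, contractility_scale)
    q[topo._oneway & (q < 0)] = 0.0
    return q


def step(
    topo: ModelTopology,
    state: ModelState,
    dt: float,
    P_intrathoracic: float = 0.0,
    r_scale: float = 1.0,
    contractility_scale: float = 1.0,
    dv0: np.ndarray | None = None,
) -> ModelState:
    """Advance the network one backward-Euler step of length ``dt``.

    Valve (and rectified-arteriole) open/closed states are taken from the
    pressures at the start of the step; volumes are then advanced implicitly
    on the resulting linear network, which conserves total volume exactly.
    """
    T = 60.0 / state.HR if state.HR > 0 else math.inf
    new_phase = (state.cardiac_phase + dt * state.HR / 60.0) % 1.0
    new_resp = (state.resp_phase + dt * state.RR / 60.0) % 1.0

    a_now = _elastance_vector(topo, state.cardiac_phase, state.arrested, T,
                              contractility_scale)
    p_now = _pressures(topo, state.V, a_now, P_intrathoracic, dv0)

    g = 1.0 / _edge_resistances(topo, r_scale, state.arrested, contractility_scale)
    closed = topo._oneway & (p_now[topo._src] <= p_now[topo._dst])
    g[closed] = 0.0

    n = topo.n
    M = np.zeros((n, n))
    src, dst = topo._src, topo._dst
    np.add.at(M, (src, src), -g)
    np.add.at(M, (src, dst), g)
    np.add.at(M, (dst, src), g)
    np.add.at(M, (dst, dst), -g)

    a_new = _elastance_vector(topo, new_phase, state.arrested, T, contractility_scale)
    v0 = _effective_v0(topo, dv0)
    pext = P_intrathoracic * topo._thoracic
    A = np.eye(n) - dt * M * a_new[None, :]
    rhs = state.V + dt * (M @ (pext - a_new * v0))
    V_new = np.linalg.solve(A, rhs)

    # sub-mL undershoots of tiny stiff chambers at beat transitions are
    # discretization grazes; abort only on clearly non-physical volumes
    if not np.all(np.isfinite(V_new)) or np.any(V_new < -1.0):
        raise SimulationError(
            f"non-physical state at t={state.t + dt:.4f}s: V={np.round(V_new, 3)}"
        )
    return ModelState(
        t=state.t + dt, V=V_new, cardiac_phase=new_phase, resp_phase=new_resp,
        HR=state.HR, RR=state.RR, arrested=state.arrested,
    )


def _intrathoracic(topo: ModelTopology, state: ModelState) -> float:
    """Ventilation waveform: mean level plus a breath-synchronous swing.
    Zero after arrest (ventilator disconnected)."""
    if state.arrested:
        return 0.0
    return topo.intrathoracic_pressure + topo.respiratory_amplitude * math.sin(
        2 * math.pi * state.resp_phase
    )


# ---------------------------------------------------------------------------
# scenario-level simulation
# ---------------------------------------------------------------------------

def mean_circulatory_filling_pressure(
    topo: ModelTopology, total_volume: float | None = None, dv0_total: float = 0.0
) -> float:
    """See :meth:`ModelTopology.mcfp`."""
    return topo.mcfp(total_volume, dv0_total)


def simulate(topo: ModelTopology, scenario, controller=None) -> HemoTrace:
    """Run baseline -> arrest -> zero-flow observation for one scenario.

    ``scenario`` provides ``volume_fraction`` (1.0 or 0.8),
    ``baseline_duration``, ``horizon_post_arrest``, ``trace_keep`` and
    ``label``.  ``controller`` (optional) is ticked at the sampling rate and
    returns the four reflex effectors; absent a controller, effectors stay
    at their base values.  ABP is taken at the abdominal aorta, CVP at the
    right atrium, CO as pulmonary-artery inflow.
    """
    total_volume = topo.total_blood_volume * scenario.volume_fraction
    state = topo.initial_state(total_volume)
    fs = topo.fs
    tick = 1.0 / fs
    n_base = int(round(scenario.baseline_duration * fs))
    n_post = int(round(scenario.horizon_post_arrest * fs))
    keep = min(scenario.trace_keep, scenario.baseline_duration)
    pa_edge = next(
        i for i, e in enumerate(topo.edges)
        if e.src == RIGHT_VENTRICLE and e.dst == PULMONARY_ARTERY
    )

    state.t = -scenario.baseline_duration
    hr, rsc, esc = topo.heart_rate, 1.0, 1.0
    dv0 = np.zeros(topo.n)

    t_out, abp, cvp, co = [], [], [], []
    base_map: list[float] = []

    # the controller engages after a short open-loop lead-in, once the beating
    # heart has pulled the network near its operating point
    lead = min(getattr(scenario, "open_loop_lead", 15.0), scenario.baseline_duration)
    warmed = controller is None
    lead_art: list[float] = []
    lead_ven: list[float] = []

    for k in range(n_base + n_post + 1):
        t = -scenario.baseline_duration + k * tick
        if not warmed and t >= -(scenario.baseline_duration - lead):
            # hand the controller the beat-averaged operating point
            n_avg = min(len(lead_art), controller.window_n) or 1
            controller.warm_start(
                float(np.mean(lead_art[-n_avg:])) if lead_art else 0.0,
                float(np.mean(lead_ven[-n_avg:])) if lead_ven else 0.0,
            )
            warmed = True
        if k == n_base:  # arrest instant
            state.arrested = True
            state.HR = 0.0
            state.RR = 0.0
            state.t = 0.0

        dt_target = topo.dt_post_arrest if state.arrested else topo.dt
        n_sub = max(1, int(round(tick / dt_target)))
        dt = tick / n_sub

        a = _elastance_vector(topo, state.cardiac_phase,
                              state.arrested, 60.0 / max(state.HR, 1e-9), esc)
        p_it = _intrathoracic(topo, state)
        p = _pressures(topo, state.V, a, p_it, dv0)

        if controller is not None and not warmed:
            lead_art.append(p[topo.aortic_arch_index])
            lead_ven.append(p[topo.right_atrium_index])
        if controller is not None and warmed:
            hr, esc, rsc, dv0 = controller.tick(
                p[topo.aortic_arch_index], p[topo.right_atrium_index]
            )
            if not state.arrested:
                state.HR = hr

        q = flows(topo, p, rsc, state.arrested, esc)
        if t >= -keep:
            t_out.append(t)
            abp.append(p[ABDOMINAL_AORTA])
            cvp.append(p[topo.right_atrium_index])
            co.append(q[pa_edge] * 0.06)  # mL/s -> L/min
        if -10.0 <= t < 0.0:
            base_map.append(p[topo.aortic_arch_index])

        for _ in range(n_sub):
            state = step(topo, state, dt, _intrathoracic(topo, state),
                         rsc, esc, dv0)

    if len(base_map) >= int(10 * fs):
        half = len(base_map) // 2
        drift = abs(np.mean(base_map[half:]) - np.mean(base_map[:half]))
        if drift > getattr(scenario, "steady_tolerance", 3.0):
            raise SimulationError(
                f"baseline did not reach a periodic steady state (mean aortic "
                f"pressure drifting {drift:.2f} mmHg per 5 s); review parameters "
                "or extend baseline_duration"
            )

    return HemoTrace(
        fs=fs, t=np.asarray(t_out), abp=np.asarray(abp), cvp=np.asarray(cvp),
        co=np.asarray(co), label=scenario.label,
    )
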