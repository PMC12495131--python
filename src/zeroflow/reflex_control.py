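"""Discrete-time arterial-baroreflex (ABR) and cardiopulmonary-reflex (CPR)
controller.

The controller runs at the signal sampling rate and closes the loop in four
stages: (I) afferent pressures from the aortic arch (pressure and pulse
pressure) and the right atrium are smoothed by a moving average over
``window_n`` samples; (II) the smoothed signals are offset against fixed set
points and the resulting errors saturated through an odd arctan
characteristic with unit slope at zero and asymptotes at the arc's scaling
limit; (III) the saturated errors are convolved with unit-area impulse
responses representing the fast (parasympathetic) and slow (sympathetic)
autonomic arcs; (IV) the efferent signals are mapped through static gains
onto the four effectors: heart rate (additive, bpm), ventricular
contractility and arteriolar resistance (fractional scale), and venous
unstressed volume (additive, mL, distributed over compartments).

Sign convention: a positive saturated error (pressure above set point) slows
the heart, reduces contractility and resistance, and raises unstressed
volume - negative-feedback physiology throughout.

The triangular kernels are evaluated recursively (the kernel's second
difference is sparse), so each tick costs O(1) regardless of kernel span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ControllerNotWarmed",
    "ReflexConfigError",
    "integrate_afferent",
    "error_signal",
    "saturate",
    "make_kernel",
    "convolve_arc",
    "apply_gains",
    "TriangularArc",
    "ReflexController",
]

EFFECTORS = ("heart_rate", "contractility", "peripheral_resistance", "unstressed_volume")


class ControllerNotWarmed(RuntimeError):
    """Afferent buffers queried before any sample was pushed."""


class ReflexConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Steps I, II and IV as plain functions
# ---------------------------------------------------------------------------

def integrate_afferent(buffer, window_n: int) -> float:
    """Step I: arithmetic mean of the last ``window_n`` samples.

    During warm-up (fewer than ``window_n`` samples) the buffer is padded
    with its first sample.
    """
    buf = np.asarray(buffer, dtype=float)
    if buf.size == 0:
        raise ControllerNotWarmed("afferent buffer is empty")
    if buf.size >= window_n:
        return float(buf[-window_n:].mean())
    pad = window_n - buf.size
    return float((buf.sum() + pad * buf[0]) / window_n)


def error_signal(integrated: float, setpoint: float) -> float:
    """Step II(a): deviation of the smoothed afferent from its set point."""
    return integrated - setpoint


def saturate(error: float, limit: float) -> float:
    """Step II(b): odd arctan saturation with unit slope at zero.

    ``phi(e) = (2L/pi) * arctan(pi * e / (2L))`` - strictly bounded by
    ``limit`` in magnitude for any input.
    """
    if limit <= 0:
        raise ReflexConfigError("saturation limit must be > 0")
    return (2.0 * limit / math.pi) * math.atan(math.pi * error / (2.0 * limit))


def make_kernel(delay: float, peak: float, end: float, fs: float) -> np.ndarray:
    """Discretize a triangular impulse response and normalize it to unit area.

    Returns the weight vector ``w`` (lag 0 .. end) with ``sum(w) == 1`` so a
    constant input reproduces itself in steady state.
    """
    d, p, e = (int(round(x * fs)) for x in (delay, peak, end))
    if not (0 <= d < p < e):
        raise ReflexConfigError(
            f"kernel breakpoints must satisfy 0 <= delay < peak < end (got {d},{p},{e} ticks)"
        )
    lags = np.arange(e + 1, dtype=float)
    w = np.interp(lags, [d, p, e], [0.0, 1.0, 0.0])
    w[: d + 1] = np.maximum(w[: d + 1], 0.0)
    return w / w.sum()


def convolve_arc(scaled_errors, kernel) -> np.ndarray:
    """Step III: causal convolution of a scaled-error sequence with a
    unit-area kernel (vectorized form, used for tests and offline work)."""
    k = np.asarray(kernel, dtype=float)
    if abs(k.sum() - 1.0) > 1e-6:
        raise ReflexConfigError(f"kernel area {k.sum():.8f} is not 1 after discretization")
    s = np.asarray(scaled_errors, dtype=float)
    return np.convolve(s, k)[: s.size]


def apply_gains(efferents: dict, gains: dict, base: dict) -> dict:
    """Step IV: map per-arc efferents onto the four effectors.

    Heart rate and unstressed volume are additive; contractility and
    peripheral resistance are multiplicative-fractional.  Outputs are
    clamped at physiological floors (HR >= 0, scales >= 0.1).
    """
    out = {}
    for eff in EFFECTORS:
        corr = sum(g * efferents[arc] for arc, g in gains.get(eff, {}).items())
        if eff == "heart_rate":
            out[eff] = max(0.0, base.get(eff, 0.0) + corr)
        elif eff == "unstressed_volume":
            out[eff] = base.get(eff, 0.0) + corr
        else:
            out[eff] = max(0.1, base.get(eff, 1.0) * (1.0 + corr))
    return out


# ---------------------------------------------------------------------------
# O(1) recursive triangular convolution
# ---------------------------------------------------------------------------

class TriangularArc:
    """One reflex arc: a unit-area triangular kernel evaluated recursively.

    The first difference of a triangular kernel is piecewise constant, so the
    efferent update needs only two moving window sums of the input history.
    """

    def __init__(self, name: str, afferent: str, limit_key: str,
                 delay: float, peak: float, end: float, fs: float):
        self.name = name
        self.afferent = afferent
        self.limit_key = limit_key
        self.weights = make_kernel(delay, peak, end, fs)
        self.d = int(round(delay * fs))
        self.p = int(round(peak * fs))
        self.e = int(round(end * fs))
        w = self.weights
        self.slope_up = w[self.d + 1] - w[self.d]
        self.slope_dn = w[self.p + 1] - w[self.p]
        self._L = self.e + 2  # history depth: lags 0 .. e+1
        self.warm_start(0.0)

    def warm_start(self, s0: float) -> None:
        """Initialize in the steady state for a constant input ``s0``."""
        self._buf = np.full(self._L, float(s0))
        self._pos = 0
        self._S1 = (self.p - self.d) * float(s0)
        self._S2 = (self.e - self.p) * float(s0)
        self.y = float(s0)

    def _lag(self, i: int) -> float:
        return self._buf[(self._pos - i) % self._L]

    def push(self, s: float) -> float:
        self._pos = (self._pos + 1) % self._L
        self._buf[self._pos] = s
        self._S1 += self._lag(self.d + 1) - self._lag(self.p + 1)
        self._S2 += self._lag(self.p + 1) - self._lag(self.e + 1)
        self.y += self.slope_up * self._S1 + self.slope_dn * self._S2
        return self.y


class _MeanBuffer:
    """Fixed-length ring buffer with an O(1) running mean."""

    def __init__(self, n: int, fill: float):
        self.n = n
        self.buf = np.full(n, float(fill))
        self.pos = 0
        self.total = float(fill) * n

    def push(self, x: float) -> None:
        self.pos = (self.pos + 1) % self.n
        self.total += x - self.buf[self.pos]
        self.buf[self.pos] = x

    @property
    def mean(self) -> float:
        return self.total / self.n


# ---------------------------------------------------------------------------
# the controller
# ---------------------------------------------------------------------------

@dataclass
class ReflexSetpoints:
    arterial_pressure: float = 95.0
    pulse_pressure: float = 35.0
    venous_pressure: float = 3.0


class ReflexController:
    """Closed-loop ABR/CPR controller, ticked once per sample.

    Construct from the ``reflex`` block of a model config.  ``tick`` takes
    the instantaneous aortic-arch and right-atrial pressures and returns
    ``(heart_rate, contractility_scale, resistance_scale, dv0_array)``.
    """

    def __init__(self, config: dict, n_compartments: int, base_heart_rate: float,
                 enabled: bool = True):
        self.enabled = enabled
        self.fs = float(config.get("tick_hz", 200.0))
        self.window_n = int(config.get("window_n", 250))
        sp = config.get("setpoints", {})
        self.setpoints = ReflexSetpoints(
            arterial_pressure=float(sp.get("arterial_pressure", 95.0)),
            pulse_pressure=float(sp.get("pulse_pressure", 35.0)),
            venous_pressure=float(sp.get("venous_pressure", 3.0)),
        )
        sat = config.get("saturation", {})
        self.limits = {"abr": float(sat.get("abr", 18.0)), "cpr": float(sat.get("cpr", 5.0))}
        self.pp_weight = float(config.get("pulse_pressure_weight", 0.25))
        self.pulse_window = int(round(float(config.get("pulse_window_s", 2.0)) * self.fs))
        self.base_heart_rate = float(base_heart_rate)
        # effector corrections fade in over this many seconds after warm
        # start, so engaging the controller cannot step the state
        self.engage_ramp_s = float(config.get("engage_ramp_s", 5.0))

        self.arcs = [
            TriangularArc(
                a["name"], a["afferent"], a.get("limit", "abr"),
                a["kernel"]["delay"], a["kernel"]["peak"], a["kernel"]["end"], self.fs,
            )
            for a in config.get("arcs", [])
        ]
        self.gains = {eff: dict(config.get("gains", {}).get(eff, {})) for eff in EFFECTORS}
        for eff, table in self.gains.items():
            for arc_name in table:
                if arc_name not in {a.name for a in self.arcs}:
                    raise ReflexConfigError(f"gain for unknown arc {arc_name!r} on {eff}")

        # distribution of the unstressed-volume effector over compartments;
        # either one table for all arcs, or per-arc tables under the arc name
        # (key "default" as fallback) - venoconstriction recruits mostly the
        # splanchnic bed, while slow tone loss may carry an arterial share
        dist = config.get("unstressed_volume_distribution", {})
        per_arc = dist and all(isinstance(k, str) for k in dist)

        def _weights(table: dict) -> np.ndarray:
            w = np.zeros(n_compartments)
            for idx, frac in table.items():
                w[int(idx)] = float(frac)
            if w.sum() > 0:
                w = w / w.sum()
            return w

        if per_arc:
            default = _weights(dist.get("default", {}))
            self.dv0_weights = {
                a.name: _weights(dist[a.name]) if a.name in dist else default
                for a in self.arcs
            }
            self.default_dv0_weights = default
        else:
            shared = _weights(dist)
            self.dv0_weights = {a.name: shared for a in self.arcs}
            self.default_dv0_weights = shared
        self._warm = False

    # -- state management -------------------------------------------------
    def warm_start(self, p_arterial: float, p_venous: float) -> None:
        """Prefill buffers and kernels with the baseline operating point.

        Pulse pressure is assumed at its set point (the pulse buffer needs a
        couple of beats before its estimate is meaningful).
        """
        self._pulse = _MeanBuffer(self.pulse_window, p_arterial)
        self._art = _MeanBuffer(self.window_n, p_arterial)
        self._ven = _MeanBuffer(self.window_n, p_venous)
        self._pp = _MeanBuffer(self.window_n, self.setpoints.pulse_pressure)
        self._pp_assumed = True
        for arc in self.arcs:
            s0 = self._scaled_error(arc, self._art.mean, self._pp.mean, self._ven.mean)
            arc.warm_start(s0)
        self._ticks = 0
        self._warm = True

    def _scaled_error(self, arc, m_art, m_pp, m_ven) -> float:
        L = self.limits[arc.limit_key]
        if arc.afferent == "arterial":
            e = error_signal(m_art, self.setpoints.arterial_pressure) + \
                self.pp_weight * error_signal(m_pp, self.setpoints.pulse_pressure)
        else:
            e = error_signal(m_ven, self.setpoints.venous_pressure)
        return saturate(e, L)

    # -- per-tick update --------------------------------------------------
    def tick(self, p_arterial: float, p_venous: float):
        if not self._warm:
            raise ControllerNotWarmed("call warm_start() before ticking the controller")
        self._pulse.push(p_arterial)
        pp = float(self._pulse.buf.max() - self._pulse.buf.min())
        self._art.push(p_arterial)
        self._ven.push(p_venous)
        self._pp.push(pp)

        if not self.enabled:
            return self.base_heart_rate, 1.0, 1.0, 0.0 * self.default_dv0_weights

        self._ticks += 1
        ramp_ticks = self.engage_ramp_s * self.fs
        ramp = min(1.0, self._ticks / ramp_ticks) if ramp_ticks > 0 else 1.0
        efferents = {
            arc.name: ramp * arc.push(
                self._scaled_error(arc, self._art.mean, self._pp.mean, self._ven.mean)
            )
            for arc in self.arcs
        }
        eff = apply_gains(
            efferents, self.gains,
            base={"heart_rate": self.base_heart_rate, "contractility": 1.0,
                  "peripheral_resistance": 1.0, "unstressed_volume": 0.0},
        )
        dv0 = np.zeros_like(self.default_dv0_weights)
        for arc_name, g in self.gains.get("unstressed_volume", {}).items():
            dv0 += g * efferents[arc_name] * self.dv0_weights[arc_name]
        return eff["heart_rate"], eff["contractility"], eff["peripheral_resistance"], dv0
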