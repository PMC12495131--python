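"""The study's in-silico scenarios: volume status x reflex activity.

Cardiac arrest is induced instantaneously at t = 0 by setting heart rate,
respiratory rate and cardiac activation to zero; intrathoracic pressure is
held at zero thereafter (ventilator disconnected).  Pentobarbital-type
arrest is modelled purely as arrest with the reflex arcs inactive; VF-type
arrest leaves them active.  Hypovolemia removes 20% of total blood volume,
proportionally from every compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cv_model
from .cv_model import HemoTrace, ModelState, ModelTopology, simulate
from .reflex_control import ReflexController

__all__ = [
    "ScenarioConfig",
    "PRESETS",
    "apply_volume_status",
    "induce_arrest",
    "make_controller",
    "run_scenario",
    "run_study",
]

VOLUME_FRACTIONS = {"euvolemia": 1.0, "hypovolemia_20pct": 0.8}

# named presets: arrest mode only differs in reflex activity
PRESETS = {
    "pento-eu": ("euvolemia", False),
    "vf-eu": ("euvolemia", True),
    "vf-hypo": ("hypovolemia_20pct", True),
    "vf-eu-noreflex": ("euvolemia", False),
    "vf-hypo-noreflex": ("hypovolemia_20pct", False),
}


@dataclass
class ScenarioConfig:
    """One simulation scenario."""

    volume_status: str = "euvolemia"
    reflexes: bool = True
    arrest_time: float = 0.0
    horizon_post_arrest: float = 601.0
    baseline_duration: float = 60.0
    trace_keep: float = 40.0
    open_loop_lead: float = 15.0
    steady_tolerance: float = 4.0  # max baseline MAP drift, mmHg per 5 s
    seed: int = 0
    calibration: str = "human_default"
    label: str = ""

    def __post_init__(self):
        if self.volume_status not in VOLUME_FRACTIONS:
            raise ValueError(f"unknown volume status {self.volume_status!r}")
        if self.horizon_post_arrest < 600.0:
            raise ValueError("horizon_post_arrest must be >= 600 s to cover the "
                             "analysis window")
        if not self.label:
            self.label = f"{self.volume_status}/{'reflex-on' if self.reflexes else 'reflex-off'}"

    @property
    def volume_fraction(self) -> float:
        return VOLUME_FRACTIONS[self.volume_status]

    @classmethod
    def from_preset(cls, name: str, **kw) -> "ScenarioConfig":
        vol, refl = PRESETS[name]
        kw.setdefault("label", name)
        return cls(volume_status=vol, reflexes=refl, **kw)


def apply_volume_status(topo: ModelTopology, state: ModelState, status: str) -> ModelState:
    """Apply the volume intervention (proportional withdrawal) before baseline."""
    if getattr(state, "_volume_status_applied", False):
        raise ValueError("volume status already applied to this state")
    frac = VOLUME_FRACTIONS[status]
    out = state.copy()
    out.V = out.V * frac
    out._volume_status_applied = True  # type: ignore[attr-defined]
    return out


def induce_arrest(state: ModelState) -> ModelState:
    """Zero-flow intervention: HR = 0, RR = 0, cardiac activation off."""
    out = state.copy()
    out.HR = 0.0
    out.RR = 0.0
    out.arrested = True
    return out


def make_controller(topo: ModelTopology, enabled: bool = True) -> ReflexController | None:
    """Build the reflex controller from the model config (None if disabled)."""
    if not enabled or not topo.reflex:
        return None
    return ReflexController(topo.reflex, topo.n, topo.heart_rate, enabled=True)


def run_scenario(topo: ModelTopology, scenario: ScenarioConfig) -> HemoTrace:
    controller = make_controller(topo, scenario.reflexes)
    return simulate(topo, scenario, controller)


def run_study(
    topo: ModelTopology | None = None,
    scenarios: dict[str, ScenarioConfig] | None = None,
) -> tuple[dict[str, HemoTrace], pd.DataFrame]:
    """Run the four study scenarios and summarize them at T0-T3.

    Returns the traces keyed by scenario name and a tidy summary table of
    the filtered signals at the four analysis time points.
    """
    from . import signal_pipeline  # deferred: avoids import cycle at module load

    if topo is None:
        topo = cv_model.build_default_model()
    if scenarios is None:
        scenarios = {
            "eu-reflex-off": ScenarioConfig("euvolemia", False, label="eu-reflex-off"),
            "eu-reflex-on": ScenarioConfig("euvolemia", True, label="eu-reflex-on"),
            "hypo-reflex-off": ScenarioConfig("hypovolemia_20pct", False,
                                              label="hypo-reflex-off"),
            "hypo-reflex-on": ScenarioConfig("hypovolemia_20pct", True,
                                             label="hypo-reflex-on"),
        }
    traces = {name: run_scenario(topo, sc) for name, sc in scenarios.items()}
    rows = []
    for name, trace in traces.items():
        summary = signal_pipeline.extract_timepoints(signal_pipeline.lowpass_mean(trace))
        for ch in ("map", "cvp", "co"):
            for tp, val in summary[ch].items():
                rows.append({"scenario": name, "channel": ch, "timepoint": tp,
                             "value": val})
    return traces, pd.DataFrame(rows)
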