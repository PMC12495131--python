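"""Synthetic pig-hemodynamics generator anchored on the experimental
group-level summary statistics.

The animal experiments are available only as group mean +/- SD at four
analysis time points (baseline -20 s, equilibration 30 s, peak 300 s,
plateau 600 s, relative to arrest).  This module synthesizes per-animal
200 Hz recordings whose group means pass exactly through those anchors:

* a deterministic group mean curve — flat baseline, a fast exponential
  transition over the first seconds of arrest, and shape-preserving
  monotone piecewise-cubic (PCHIP) interpolation through the post-arrest
  anchors;
* a pulsatile carrier before arrest (so the 0.5 Hz low-pass filter of the
  processing chain has realistic work to do) — a synthetic convention, not
  a physiological waveform model;
* per-animal offsets scaled by the anchor-interpolated SD trajectory
  (between-animal dispersion, correlated across channels) plus band-limited
  within-trace noise;
* CO drops to zero at the arrest instant (no-flow by definition).

Everything is deterministic per seed, with independent per-animal
substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, lfilter

from .cv_model import HemoTrace

__all__ = [
    "AnchorTable",
    "CohortSpec",
    "load_anchor_table",
    "group_mean_curve",
    "group_sd_curve",
    "synthesize_animal",
    "synthesize_cohort",
]

GROUPS = ("pento_eu", "vf_eu", "vf_hypo")
CHANNELS = ("map", "cvp", "co")
_GROUP_INDEX = {g: i for i, g in enumerate(GROUPS)}


@dataclass(frozen=True)
class AnchorTable:
    """Mean/SD of each group and channel at the four analysis times."""

    times: np.ndarray
    data: dict  # group -> channel -> {"mean": array, "sd": array}
    source_text: str = ""

    def mean(self, group: str, channel: str) -> np.ndarray:
        return np.asarray(self.data[group][channel]["mean"], dtype=float)

    def sd(self, group: str, channel: str) -> np.ndarray:
        return np.asarray(self.data[group][channel]["sd"], dtype=float)

    def checksum(self) -> str:
        payload = json.dumps(
            {g: {c: {k: list(map(float, v)) for k, v in self.data[g][c].items()}
                 for c in CHANNELS} for g in GROUPS},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self) -> "AnchorTable":
        for g in GROUPS:
            for c in CHANNELS:
                m, s = self.mean(g, c), self.sd(g, c)
                if m.shape != (4,) or s.shape != (4,):
                    raise ValueError(f"anchor table {g}/{c}: need 4 time points")
                if np.any(s < 0):
                    raise ValueError(f"anchor table {g}/{c}: negative SD")
        return self


def load_anchor_table(path: str | None = None) -> AnchorTable:
    """Load the packaged anchor table (or an alternative YAML file)."""
    if path is None:
        text = resources.files("zeroflow.config").joinpath("table1_anchors.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    data = {
        g: {c: {"mean": raw["groups"][g][c]["mean"], "sd": raw["groups"][g][c]["sd"]}
            for c in CHANNELS}
        for g in raw["groups"]
    }
    return AnchorTable(
        times=np.asarray(raw["times_s"], dtype=float), data=data, source_text=text
    ).validate()


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout, carrier and noise model of the synthetic recordings."""

    n_per_group: dict = field(
        default_factory=lambda: {"pento_eu": 7, "vf_eu": 4, "vf_hypo": 3}
    )
    fs: float = 200.0
    baseline_s: float = 60.0
    end_s: float = 601.0
    heart_rate_bpm: float = 100.0
    pulse_pressure: float = 30.0       # synthetic systolic-diastolic excursion
    cvp_pulse: float = 2.0
    co_pulse_frac: float = 0.5
    transition_tau_s: float = 4.0      # fast post-arrest equilibration
    offset_rho: float = 0.8            # cross-channel correlation of animal offsets
    noise_sd: float = 2.0              # within-trace pressure noise, mmHg
    co_noise_sd: float = 0.005         # post/pre-arrest CO noise, L/min
    noise_scale: float = 1.0           # 0 => noiseless (offsets and noise off)
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g}: need n >= 2 for statistics (got {n})")
        if self.fs <= 1.0:
            raise ValueError("fs must exceed twice the 0.5 Hz analysis cutoff")

    def noiseless(self) -> "CohortSpec":
        return replace(self, noise_scale=0.0)


# ---------------------------------------------------------------------------
# deterministic group curves
# ---------------------------------------------------------------------------

def _anchored_curve(times: np.ndarray, values: np.ndarray, tau: float):
    """Curve through the four anchors: flat before arrest, exponential
    transition blended so the value at the first post-arrest anchor is exact,
    PCHIP beyond it, clamped flat outside the anchor span."""
    t0, t1 = times[0], times[1]
    v0, v1 = values[0], values[1]
    interp = PchipInterpolator(times[1:], values[1:], extrapolate=False)
    decay_end = np.exp(-t1 / tau)

    def f(t):
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        pre = t <= 0.0
        out[pre] = v0
        trans = (t > 0.0) & (t < t1)
        tt = t[trans]
        out[trans] = v1 + (v0 - v1) * (np.exp(-tt / tau) - (tt / t1) * decay_end)
        post = t >= t1
        out[post] = interp(np.clip(t[post], t1, times[-1]))
        return out

    return f


def group_mean_curve(group: str, channel: str, anchors: AnchorTable,
                     tau: float = 4.0):
    """Continuous group-mean trajectory on [-60, 601] s.

    MAP/CVP: flat baseline at the T0 mean, fast exponential transition to the
    30 s anchor, monotone-segment PCHIP through the 30/300/600 s anchors.
    CO: baseline mean before arrest, exactly zero after (no-flow).
    Evaluating at the anchor times returns the anchor means.
    """
    means = anchors.mean(group, channel)
    if channel == "co":
        baseline = means[0]

        def f(t):
            t = np.asarray(t, dtype=float)
            return np.where(t < 0.0, baseline, 0.0)

        return f
    return _anchored_curve(anchors.times, means, tau)


def group_sd_curve(group: str, channel: str, anchors: AnchorTable):
    """Between-animal SD as a function of time (PCHIP through the anchor SDs,
    clamped outside the anchor span)."""
    times, sds = anchors.times, anchors.sd(group, channel)
    interp = PchipInterpolator(times, sds, extrapolate=False)

    def f(t):
        t = np.asarray(t, dtype=float)
        return interp(np.clip(t, times[0], times[-1]))

    return f


# ---------------------------------------------------------------------------
# per-animal synthesis
# ---------------------------------------------------------------------------

def _band_limited_noise(rng, n, fs, sd):
    """White Gaussian noise shaped by a gentle 5 Hz low-pass, renormalized."""
    white = rng.standard_normal(n)
    b, a = butter(2, min(5.0, 0.45 * fs), fs=fs)
    shaped = lfilter(b, a, white)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def _animal_rng(spec: CohortSpec, group: str, animal_id: int):
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, _GROUP_INDEX[group], animal_id])
    )


def synthesize_animal(group: str, animal_id: int, spec: CohortSpec,
                      anchors: AnchorTable) -> HemoTrace:
    """One synthetic animal recording (ABP, CVP, CO at ``spec.fs``)."""
    rng = _animal_rng(spec, group, animal_id)
    n = int(round((spec.end_s + spec.baseline_s) * spec.fs)) + 1
    t = -spec.baseline_s + np.arange(n) / spec.fs
    pre = t < 0.0

    # correlated per-animal offsets: one shared factor plus channel-specific
    z_shared = rng.standard_normal()
    z = {
        ch: spec.offset_rho * z_shared
        + np.sqrt(1.0 - spec.offset_rho**2) * rng.standard_normal()
        for ch in CHANNELS
    }

    phase = 2 * np.pi * (spec.heart_rate_bpm / 60.0) * t
    carrier = {
        "map": (spec.pulse_pressure / 2.0) * np.sin(phase) * pre,
        "cvp": (spec.cvp_pulse / 2.0) * np.sin(phase + np.pi / 3) * pre,
        "co": None,  # filled below (proportional to the mean)
    }

    channels = {}
    for ch in CHANNELS:
        mean = group_mean_curve(group, ch, anchors, spec.transition_tau_s)(t)
        sd_t = group_sd_curve(group, ch, anchors)(t)
        if ch == "co":
            wave = spec.co_pulse_frac * mean * np.sin(phase) * pre
            noise_sd = spec.co_noise_sd
            sd_t = sd_t * pre  # no flow, no between-animal spread after arrest
        else:
            wave = carrier[ch]
            noise_sd = spec.noise_sd
        noise = _band_limited_noise(rng, n, spec.fs, noise_sd) * spec.noise_scale
        offset = z[ch] * sd_t * spec.noise_scale
        channels[ch] = mean + wave + offset + noise

    return HemoTrace(
        fs=spec.fs, t=t, abp=channels["map"], cvp=channels["cvp"],
        co=channels["co"], label=f"{group}/animal{animal_id:02d}",
    )


def synthesize_cohort(
    spec: CohortSpec | None = None,
    anchors: AnchorTable | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[HemoTrace]], dict]:
    """Synthesize every animal of every group; optionally write CSVs.

    Returns the traces grouped by cohort plus a manifest (group layout,
    seed, anchor-table checksum, output files).
    """
    spec = spec or CohortSpec()
    anchors = anchors or load_anchor_table()
    traces: dict[str, list[HemoTrace]] = {}
    files: list[str] = []
    for group, n_animals in spec.n_per_group.items():
        traces[group] = [
            synthesize_animal(group, i, spec, anchors) for i in range(n_animals)
        ]
    manifest = {
        "groups": {g: len(v) for g, v in traces.items()},
        "fs_hz": spec.fs,
        "seed": spec.seed,
        "noise_scale": spec.noise_scale,
        "anchor_checksum": anchors.checksum(),
        "files": files,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for group, group_traces in traces.items():
            for i, tr in enumerate(group_traces):
                path = out / f"{group}_animal{i:02d}.csv"
                try:
                    tr.to_csv(path)
                except OSError as exc:
                    raise OSError(f"failed writing synthetic trace {path}: {exc}") from exc
                files.append(path.name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return traces, manifest
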