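"""Processing and comparison chain for zero-flow hemodynamic recordings.

Mirrors the experimental data handling: mean signals are obtained by a
third-order Butterworth low-pass at 0.5 Hz applied forward and backward
(zero phase, squared magnitude response); four analysis points are read off
the mean curves (baseline -20 s, equilibration 30 s, peak 300 s, plateau
600 s); model-data agreement is quantified by a normalized RMSE (reference
range normalization, in percent, <5% read as high agreement); and group
contrasts are tested with repeated-measures ANOVA, a mixed
(group x time) ANOVA, paired t-tests and Shapiro-Wilk normality screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .cv_model import HemoTrace

__all__ = [
    "TIMEPOINTS",
    "TimepointSummary",
    "lowpass_mean",
    "extract_timepoints",
    "normalized_rmse",
    "trace_nrmse",
    "cohort_summary",
    "group_statistics",
]

TIMEPOINTS = (-20.0, 30.0, 300.0, 600.0)
CHANNELS = ("map", "cvp", "co")


@dataclass
class TimepointSummary:
    """Channel values at the four analysis time points."""

    values: dict = field(default_factory=dict)  # channel -> {time: value}
    label: str = ""

    def __getitem__(self, channel: str) -> dict:
        return self.values[channel]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": ch, "timepoint": tp, "value": v, "label": self.label}
            for ch, tps in self.values.items()
            for tp, v in tps.items()
        ]
        return pd.DataFrame(rows)


def lowpass_mean(trace: HemoTrace, cutoff: float = 0.5, order: int = 3) -> HemoTrace:
    """Zero-phase Butterworth low-pass of all channels (the "mean" signals).

    Forward-backward application doubles the effective order and squares the
    magnitude response; edges are handled by reflecting the record about its
    end points.
    """
    if trace.fs <= 2.0 * cutoff:
        raise ValueError(f"sampling rate {trace.fs} Hz too low for a {cutoff} Hz cutoff")
    min_len = int(np.ceil(6.0 * trace.fs / cutoff))
    if len(trace.t) <= min_len:
        raise ValueError(
            f"trace too short for stable zero-phase filtering: need more than "
            f"{min_len} samples at fs={trace.fs} Hz, got {len(trace.t)}"
        )
    b, a = sps.butter(order, cutoff, fs=trace.fs)
    return HemoTrace(
        fs=trace.fs,
        t=trace.t,
        abp=sps.filtfilt(b, a, trace.abp),
        cvp=sps.filtfilt(b, a, trace.cvp),
        co=sps.filtfilt(b, a, trace.co),
        label=trace.label,
    )


def extract_timepoints(
    mean_trace: HemoTrace,
    times: tuple = TIMEPOINTS,
    half_window: float = 1.0,
) -> TimepointSummary:
    """Read the mean signals at the analysis times (+/- 1 s window average,
    damping any residual ripple).  The trace must span all requested times;
    a window clipped by the record end is averaged over its available part."""
    t = mean_trace.t
    if t[0] > min(times) or t[-1] < max(times):
        raise ValueError(
            f"trace spans [{t[0]:.1f}, {t[-1]:.1f}] s but time points "
            f"{list(times)} were requested"
        )
    values: dict = {ch: {} for ch in CHANNELS}
    for tp in times:
        sel = (t >= tp - half_window) & (t <= tp + half_window)
        for ch in CHANNELS:
            values[ch][tp] = float(mean_trace.channel(ch)[sel].mean())
    return TimepointSummary(values=values, label=mean_trace.label)


def normalized_rmse(
    sim: np.ndarray,
    ref: np.ndarray,
    t_sim: np.ndarray | None = None,
    t_ref: np.ndarray | None = None,
    window: tuple = (0.0, 600.0),
    normalization: str = "range",
) -> float:
    """RMSE between a simulated and a reference mean curve, in percent.

    If time vectors are given, the simulated curve is resampled onto the
    reference grid restricted to ``window``.  The error is normalized by the
    reference range over the window (``normalization="mean"`` divides by the
    reference mean instead).
    """
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if t_sim is not None and t_ref is not None:
        sel = (t_ref >= window[0]) & (t_ref <= window[1])
        ref = ref[sel]
        sim = np.interp(t_ref[sel], t_sim, sim)
    if sim.shape != ref.shape:
        raise ValueError("sim and ref must share a common grid (pass time vectors)")
    rmse = float(np.sqrt(np.mean((sim - ref) ** 2)))
    if normalization == "range":
        denom = float(ref.max() - ref.min())
    elif normalization == "mean":
        denom = float(abs(ref.mean()))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0.0:
        raise ValueError("reference range is zero; normalized RMSE undefined")
    return 100.0 * rmse / denom


def trace_nrmse(
    sim: HemoTrace,
    ref: HemoTrace,
    channels: tuple = ("map", "cvp"),
    window: tuple = (0.0, 600.0),
    normalization: str = "range",
) -> dict:
    """Per-channel normalized RMSE between two mean traces plus the mean
    across channels."""
    out = {}
    for ch in channels:
        out[ch] = normalized_rmse(
            sim.channel(ch), ref.channel(ch), sim.t, ref.t, window, normalization
        )
    out["mean"] = float(np.mean([out[ch] for ch in channels]))
    return out


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def cohort_summary(traces_by_group: dict) -> pd.DataFrame:
    """Filter every animal trace and extract the time points.

    Returns a tidy frame with columns group, animal, channel, timepoint,
    value - the input format of :func:`group_statistics`.
    """
    rows = []
    for group, traces in traces_by_group.items():
        for i, tr in enumerate(traces):
            summ = extract_timepoints(lowpass_mean(tr))
            for ch in CHANNELS:
                for tp, v in summ[ch].items():
                    rows.append(
                        {"group": group, "animal": f"{group}_{i:02d}",
                         "channel": ch, "timepoint": tp, "value": v}
                    )
    return pd.DataFrame(rows)


def group_statistics(
    summaries: pd.DataFrame,
    reference_group: str = "pento_eu",
    alpha: float = 0.05,
) -> dict:
    """The prespecified contrasts on the time-point summaries.

    * within-group change over 30-600 s: one-way repeated-measures ANOVA per
      group and channel;
    * group x time interaction against the reference (pentobarbital) group:
      mixed ANOVA (time within, group between);
    * arterio-venous difference at 600 s: paired t-test MAP vs CVP per group;
    * Shapiro-Wilk normality screens on the 600 s values.

    Test mathematics are delegated to pingouin/scipy; all p-values are
    two-sided.
    """
    import pingouin as pg

    df = summaries.copy()
    if not np.isfinite(df["value"]).all():
        raise ValueError("non-finite values in time-point summaries")
    for group, sub in df.groupby("group"):
        if sub["animal"].nunique() < 2:
            raise ValueError(f"group {group}: need at least 2 subjects")

    post = df[df["timepoint"] > 0.0]
    results: dict = {"alpha": alpha}

    def _p(frame):
        col = "p_unc" if "p_unc" in frame.columns else "p-unc"
        return frame[col]

    rows = []
    for (group, ch), sub in post.groupby(["group", "channel"]):
        aov = pg.rm_anova(data=sub, dv="value", within="timepoint", subject="animal")
        rows.append({
            "group": group, "channel": ch,
            "F": float(aov["F"].iloc[0]), "p": float(_p(aov).iloc[0]),
        })
    results["within_time"] = pd.DataFrame(rows)

    rows = []
    for group in sorted(set(df["group"]) - {reference_group}):
        for ch in ("map", "cvp", "co"):
            sub = post[(post["group"].isin([group, reference_group]))
                       & (post["channel"] == ch)]
            aov = pg.mixed_anova(data=sub, dv="value", within="timepoint",
                                 subject="animal", between="group")
            inter = aov[aov["Source"] == "Interaction"]
            rows.append({
                "group": group, "channel": ch,
                "F": float(inter["F"].iloc[0]), "p": float(_p(inter).iloc[0]),
            })
    results["interaction_vs_reference"] = pd.DataFrame(rows)

    rows = []
    for group, sub in df[df["timepoint"] == 600.0].groupby("group"):
        wide = sub.pivot_table(index="animal", columns="channel", values="value")
        t_res = stats.ttest_rel(wide["cvp"], wide["map"])
        sw = stats.shapiro(wide["cvp"] - wide["map"])
        rows.append({
            "group": group,
            "mean_cvp_minus_map": float((wide["cvp"] - wide["map"]).mean()),
            "t": float(t_res.statistic), "p": float(t_res.pvalue),
            "shapiro_p": float(sw.pvalue),
        })
    results["paired_cvp_vs_map_t600"] = pd.DataFrame(rows)

    rows = []
    for (group, ch), sub in df[df["timepoint"] == 600.0].groupby(["group", "channel"]):
        vals = sub["value"].to_numpy()
        if np.ptp(vals) == 0:
            continue  # degenerate (e.g. CO identically zero after arrest)
        sw = stats.shapiro(vals)
        rows.append({"group": group, "channel": ch, "W": float(sw.statistic),
                     "p": float(sw.pvalue)})
    results["shapiro_t600"] = pd.DataFrame(rows)
    return results
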