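"""Static figures: VPC overlays, goodness-of-fit wedge, exposure box plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_vpc(vpc_result: dict, ax=None, log_scale: bool = True):
    """Percentile bands with the observed overlay (if present)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    bands = vpc_result["bands"]
    t = bands["time_h"]
    ax.fill_between(t, bands["p5"], bands["p95"], alpha=0.25,
                    label="5–95th percentile")
    ax.plot(t, bands["mean"], lw=2, label="simulated mean")
    ax.plot(t, bands["min"], ls="--", lw=0.8, color="gray")
    ax.plot(t, bands["max"], ls="--", lw=0.8, color="gray", label="min/max")
    if "overlay" in vpc_result:
        ov = vpc_result["overlay"]
        ax.plot(ov["time_h"], ov["observed"], "o", ms=5, color="k",
                label="observed")
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.legend()
    return ax


def plot_goodness_of_fit(per_profile: pd.DataFrame, ax=None):
    """Predicted vs observed scatter with the two-fold acceptance wedge."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    obs = per_profile["observed"].to_numpy(dtype=float)
    pred = per_profile["predicted"].to_numpy(dtype=float)
    lo = min(obs.min(), pred.min()) * 0.5
    hi = max(obs.max(), pred.max()) * 2.0
    line = np.array([lo, hi])
    ax.plot(line, line, "k-", lw=1, label="unity")
    ax.plot(line, 2 * line, "k--", lw=0.8, label="2-fold")
    ax.plot(line, 0.5 * line, "k--", lw=0.8)
    ax.plot(obs, pred, "o", ms=6)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("observed")
    ax.set_ylabel("predicted")
    ax.legend()
    return ax


def plot_exposure_boxes(summary: pd.DataFrame, metric: str = "total", ax=None):
    """Box-and-whisker exposure comparison (5–95th whiskers)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    rows = summary[summary["metric"] == metric]
    stats = [{
        "label": f"{r.label}\n{r.dose_mg:g} mg", "med": r.median,
        "q1": r.q1, "q3": r.q3, "whislo": r.p5, "whishi": r.p95,
        "mean": r["mean"], "fliers": [],
    } for _, r in rows.iterrows()]
    ax.bxp(stats, showmeans=True)
    ax.set_ylabel(f"AUC0–inf {metric} (ng·h/mL)")
    return ax
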