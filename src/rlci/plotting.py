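"""Plotting helpers mirroring the standard figure layouts of the analysis:
classification-image heat maps with center/surround impact curves below,
RT-versus-cue-onset epoch plots, and peak-impact-by-epoch summaries."""

from __future__ import annotations

import numpy as np

from .ci import ClassificationImage, ImpactCurves

__all__ = [
    "plot_classification_image",
    "plot_impact_curves",
    "plot_rt_epochs",
    "plot_peak_impact",
]


def plot_classification_image(ci: ClassificationImage, ax=None, **imshow_kw):
    """Heat map of CI weights: space (bars) vertical, backward time horizontal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = np.nanmax(np.abs(ci.weights)) or 1.0
    im = ax.imshow(
        ci.weights,
        aspect="auto",
        origin="lower",
        extent=[ci.lag_ms[0], ci.lag_ms[-1], 0.5, ci.weights.shape[0] + 0.5],
        cmap="gray",
        vmin=-v,
        vmax=v,
        **imshow_kw,
    )
    ax.set_xlabel("time before response (ms)")
    ax.set_ylabel("bar")
    ax.invert_xaxis()
    return im


def plot_impact_curves(curves: ImpactCurves, ax=None, label_prefix=""):
    """Center (red) and surround (blue) weights vs time before response."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for trace, sem, color, name in (
        (curves.center, curves.center_sem, "tab:red", "center"),
        (curves.surround, curves.surround_sem, "tab:blue", "surround"),
    ):
        ax.plot(curves.lag_ms, trace, color=color, label=label_prefix + name)
        if sem is not None:
            ax.fill_between(
                curves.lag_ms, trace - sem, trace + sem, color=color, alpha=0.25, lw=0
            )
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time before response (ms)")
    ax.set_ylabel("impact (contrast)")
    ax.invert_xaxis()
    ax.legend(frameon=False)
    return ax


def plot_rt_epochs(table, ax=None):
    """Mean RT per cue-onset epoch, one line per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"valid": "tab:red", "invalid": "tab:blue", "no_cue": "k"}
    for cond, sub in table.groupby("condition"):
        sub = sub.dropna(subset=["epoch_start_ms"])
        if not len(sub):
            continue
        x = (sub["epoch_start_ms"] + sub["epoch_end_ms"]) / 2
        ax.plot(x, sub["mean_rt_ms"], color=colors.get(cond, "gray"), label=cond)
        ax.fill_between(
            x,
            sub["mean_rt_ms"] - sub["sem_ms"],
            sub["mean_rt_ms"] + sub["sem_ms"],
            color=colors.get(cond, "gray"),
            alpha=0.25,
            lw=0,
        )
    ax.set_xlabel("cue onset epoch (ms)")
    ax.set_ylabel("harmonic-mean RT (ms)")
    ax.legend(frameon=False)
    return ax


def plot_peak_impact(table, ax=None):
    """Peak impact (mean over the 300-400 ms window) per cue epoch."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"valid": "tab:red", "invalid": "tab:blue"}
    for cond, sub in table.groupby("condition"):
        x = (sub["epoch_start_ms"] + sub["epoch_end_ms"]) / 2
        ax.errorbar(
            x,
            sub["peak_center"],
            yerr=sub.get("peak_center_sem"),
            color=colors.get(cond, "gray"),
            marker="o",
            label=f"{cond} center",
        )
        ax.plot(
            x,
            sub["peak_surround"],
            color=colors.get(cond, "gray"),
            ls="--",
            label=f"{cond} surround",
        )
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from response to cue onset (ms)")
    ax.set_ylabel("peak impact (contrast)")
    ax.legend(frameon=False, fontsize=8)
    return ax
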