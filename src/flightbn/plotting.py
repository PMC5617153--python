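"""Diagnostic plots: modified Type-II ROC, CV error envelopes, tornado."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_type2_roc(curves: pd.DataFrame, ax=None, label=None):
    """True-negative prediction rate vs Type II error, one point per
    threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curves["type2_pct"], curves["true_negative_rate_pct"], label=label)
    ax.set_xlabel("Type II (false negative) error rate (%)")
    ax.set_ylabel("True-negative prediction rate (%)")
    if label:
        ax.legend()
    return ax


def plot_cv_envelope(cv, error_type: str = "type2_pct", ax=None):
    """Calibration curve against the CV mean +- 1 SD band and min/max
    envelope, with the SD-distance diagnostic on a twin axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid = cv.grid
    stats = cv.stats[error_type]
    ax.fill_between(grid, stats["min"], stats["max"], color="gold", alpha=0.4, label="min-max")
    ax.fill_between(
        grid,
        stats["mean"] - stats["sd"],
        stats["mean"] + stats["sd"],
        color="steelblue",
        alpha=0.4,
        label="+-1 SD",
    )
    ax.plot(grid, stats["mean"], color="white", lw=1)
    ax.plot(grid, cv.calibration[error_type], color="red", lw=1.2, label="calibration")
    ax2 = ax.twinx()
    ax2.plot(grid, cv.sd_distance[error_type], color="green", lw=0.8)
    ax2.set_ylabel("SD distance", color="green")
    ax.set_xlabel("no-flight threshold")
    ax.set_ylabel(f"{error_type} (%)")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_tornado(frame: pd.DataFrame, ax=None):
    """Grey bars: potential reduction below the normative baseline; black
    bars: potential increase above it."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(frame) + 1))
    ypos = np.arange(len(frame))[::-1]
    base = frame["baseline"].to_numpy()
    ax.barh(ypos, base - frame["min"], left=frame["min"], color="0.6")
    ax.barh(ypos, frame["max"] - base, left=base, color="black")
    ax.axvline(base[0], color="red", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(frame["variable"])
    ax.set_xlabel("P(flight)")
    return ax
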