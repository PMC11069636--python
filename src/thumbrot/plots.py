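"""Matplotlib views of the evaluation and attribution artifacts."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt

__all__ = ["residual_plot", "correlation_heatmap", "importance_bar"]


def residual_plot(report, ax=None):
    """Residuals (actual - predicted) against the actual angle."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    pairs = report.residual_pairs
    ax.scatter(pairs["true_angle"], pairs["residual"], s=8, alpha=0.4)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("actual angle (deg)")
    ax.set_ylabel("residual (deg)")
    ax.set_title(f"{report.family}: RMSE {report.rmse:.2f} deg")
    return ax


def correlation_heatmap(corr, ax=None):
    """Heatmap of a feature correlation matrix (warm = positive)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr.index)), corr.index)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.figure.tight_layout()
    return ax


def importance_bar(attribution, ax=None):
    """Horizontal bar chart of an attribution result, largest first."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    frame = attribution.to_frame().iloc[::-1]
    ax.barh(frame["feature"], frame["value"])
    label = "importance share" if attribution.kind == "importance" else "Shapley value (deg)"
    ax.set_xlabel(label)
    ax.figure.tight_layout()
    return ax
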