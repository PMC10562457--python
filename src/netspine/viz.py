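"""Plots over comparison tables: radar, progression lines, distributions.

The plotted numbers are exactly the tables produced by the compare module;
the figures are a presentation layer only.
"""

from __future__ import annotations

import math
from os import PathLike

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["radar_plot", "progression_plot", "distribution_plot"]


def radar_plot(table: pd.DataFrame, path: str | PathLike) -> None:
    """Radar chart of a property table: one axis per measure, one polygon
    per network row."""
    if table.empty:
        raise ValueError("empty property table")
    measures = list(table.columns)
    angles = [2 * math.pi * i / len(measures) for i in range(len(measures))]
    angles_closed = angles + angles[:1]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    for name, row in table.iterrows():
        values = row.tolist()
        ax.plot(angles_closed, values + values[:1], label=str(name))
        ax.fill(angles_closed, values + values[:1], alpha=0.08)
    ax.set_xticks(angles)
    ax.set_xticklabels(measures)
    ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def progression_plot(
    series: pd.DataFrame, path: str | PathLike, *, ylabel: str = ""
) -> None:
    """Line chart of a progression table (rows = parameter values,
    columns = methods)."""
    if series.empty:
        raise ValueError("empty progression table")
    fig, ax = plt.subplots(figsize=(7, 5))
    for column in series.columns:
        ax.plot(series.index, series[column], marker="o", label=str(column))
    ax.set_xlabel("filter parameter")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def distribution_plot(samples: dict, path: str | PathLike, *, xlabel: str = "") -> None:
    """Scatter chart of empirical cumulative distributions, one per sample.

    ``samples`` maps a label to a sequence of values.
    """
    if not samples:
        raise ValueError("no samples to plot")
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, values in samples.items():
        x = np.sort(np.asarray(list(values), dtype=float))
        if x.size == 0:
            raise ValueError(f"empty sample {label!r}")
        cdf = np.arange(1, x.size + 1) / x.size
        ax.scatter(x, cdf, s=12, label=str(label))
    ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative fraction")
    ax.legend(fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
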