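"""Static publication-style figures: fitted curves, curve grids, boxplots,
metric-vs-metric scatterplots.

Every figure is a derived view of a machine-readable table written
alongside it; plotting never computes anything the tables do not contain.
Figures are saved in both vector (PDF) and bitmap (PNG) form.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .compare import GroupSummary
from .fitting import ConditionResult, logistic

#: points in the smooth curve overlay
CURVE_GRID_N = 100
#: extension of the drawn range beyond the tested range, in log10 units
CURVE_GRID_PAD = 0.5


def _save(fig, path_base: str, formats: Sequence[str] = ("pdf", "png")) -> List[str]:
    paths = []
    for ext in formats:
        p = f"{path_base}.{ext}"
        fig.savefig(p)
        paths.append(p)
    plt.close(fig)
    return paths


def curve_grid_concentrations(conc: np.ndarray) -> np.ndarray:
    lo = math.log10(conc.min()) - CURVE_GRID_PAD
    hi = math.log10(conc.max()) + CURVE_GRID_PAD
    return np.logspace(lo, hi, CURVE_GRID_N)


def _draw_condition(ax, res: ConditionResult, scale: str) -> None:
    conc = res.series.concentrations
    if scale == "gr":
        y, fit = res.series.gr_values, res.gr_fit
        params = (fit.gr_inf, fit.gec50, fit.h_gr)
    else:
        y, fit = res.series.relative_counts, res.trad_fit
        params = (fit.e_inf, fit.ec50, fit.h)
    grid = curve_grid_concentrations(conc)
    if fit.flat_fit:
        curve = np.full_like(grid, fit.flat_level)
    else:
        curve = logistic(grid, *params)
    ax.plot(grid, curve, "-", lw=1.5)
    ax.plot(conc, y, "o", ms=4)
    ax.set_xscale("log")
    ax.axhline(0.0 if scale == "gr" else 0.5, color="0.8", lw=0.8, zorder=0)


def plot_condition_curve(res: ConditionResult, path_base: str,
                         scale: str = "gr") -> List[str]:
    """One dose-response panel: measured points plus the fitted curve."""
    fig, ax = plt.subplots(figsize=(4, 3))
    _draw_condition(ax, res, scale)
    ax.set_xlabel("concentration")
    ax.set_ylabel("GR value" if scale == "gr" else "relative cell count")
    ax.set_title(res.series.label, fontsize=9)
    fig.tight_layout()
    return _save(fig, path_base)


def plot_curve_grid(results: Sequence[ConditionResult], grid_key: str,
                    path_base: str, scale: str = "gr") -> List[str]:
    """Grid of dose-response panels, one per value of ``grid_key``.

    Each panel overlays the curves of every condition sharing that value
    (e.g. grid by drug, curves colored by cell line).
    """
    if not results:
        raise ValueError("no results to plot")
    keys = results[0].series.condition_keys
    if grid_key not in keys:
        raise ValueError(f"grid key {grid_key!r} not among grouping keys {keys}")
    idx = keys.index(grid_key)
    panels: Dict[str, List[ConditionResult]] = {}
    for r in results:
        panels.setdefault(r.series.condition_id[idx], []).append(r)
    n = len(panels)
    ncol = math.ceil(math.sqrt(n))
    nrow = math.ceil(n / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for ax, (value, members) in zip(axes.flat, panels.items()):
        for r in members:
            _draw_condition(ax, r, scale)
        ax.set_title(f"{grid_key} = {value}", fontsize=9)
    fig.supxlabel("concentration")
    fig.supylabel("GR value" if scale == "gr" else "relative cell count")
    fig.tight_layout()
    return _save(fig, path_base)


def plot_metric_boxplot(groups: Dict[str, np.ndarray],
                        summaries: Sequence[GroupSummary],
                        metric_name: str, path_base: str,
                        p_value: Optional[float] = None) -> List[str]:
    """Boxplots of one metric per group, annotated with the rank-sum p."""
    finite = {g: v[np.isfinite(v)] for g, v in groups.items()}
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(groups), 3.2))
    ax.boxplot([finite[g] for g in groups], tick_labels=list(groups), whis=1.5)
    ax.set_ylabel(metric_name)
    if p_value is not None:
        ax.set_title(f"Wilcoxon rank-sum p = {p_value:.3g}", fontsize=9)
    fig.tight_layout()
    return _save(fig, path_base)


def plot_metric_scatter(metrics: pd.DataFrame, x_metric: str, y_metric: str,
                        path_base: str,
                        color_key: Optional[str] = None) -> List[str]:
    """Scatter of one metric against another across conditions."""
    fig, ax = plt.subplots(figsize=(3.6, 3.2))
    x = pd.to_numeric(metrics[x_metric], errors="coerce")
    y = pd.to_numeric(metrics[y_metric], errors="coerce")
    if color_key is not None:
        for value, sub in metrics.groupby(color_key):
            ax.plot(x[sub.index], y[sub.index], "o", ms=4, label=str(value))
        ax.legend(fontsize=7)
    else:
        ax.plot(x, y, "o", ms=4)
    ax.set_xlabel(x_metric)
    ax.set_ylabel(y_metric)
    fig.tight_layout()
    return _save(fig, path_base)
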