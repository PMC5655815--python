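"""Compare metric distributions between groups of conditions.

Typical use: restrict a metrics table to one agent and tissue, split the
conditions by a metadata variable (e.g. mutation status), and test whether
the two groups' GR50 distributions differ with a two-sided Wilcoxon
rank-sum (Mann-Whitney) test — a robust alternative to the t-test that
tolerates the +Inf values produced by capped or never-crossing potency
metrics, since only ranks matter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSelection", "EmptySelectionError", "filter_metrics",
    "rank_sum_test", "boxplot_summary", "GroupSummary",
]

#: exact Mann-Whitney enumeration is used up to this per-group size
EXACT_N_MAX = 20


class EmptySelectionError(ValueError):
    """Filtering left no rows to compare."""


@dataclass
class MetricSelection:
    """What to compare: which metric, which rows, and how to group them."""

    metric_name: str
    group_key: str
    filter: Dict[str, List[str]] = field(default_factory=dict)
    shown_groups: Optional[List[str]] = None

    def __post_init__(self):
        if self.group_key in self.filter:
            raise ValueError("group_key cannot also be a filter key")


def filter_metrics(
    metrics: pd.DataFrame, selection: MetricSelection
) -> Dict[str, np.ndarray]:
    """Partition one metric column by group, after metadata filtering.

    Missing (NA) metric values are dropped with a logged count; infinite
    values are retained (they carry rank information).  Group order follows
    first appearance unless ``shown_groups`` fixes it.
    """
    if selection.metric_name not in metrics.columns:
        raise KeyError(
            f"unknown metric {selection.metric_name!r}; available: "
            f"{list(metrics.columns)}"
        )
    if selection.group_key not in metrics.columns:
        raise KeyError(f"unknown grouping column {selection.group_key!r}")
    df = metrics
    for key, allowed in selection.filter.items():
        if key not in df.columns:
            raise KeyError(f"unknown filter column {key!r}")
        allowed = [allowed] if isinstance(allowed, str) else list(allowed)
        df = df[df[key].astype(str).isin([str(a) for a in allowed])]
    if df.empty:
        raise EmptySelectionError("no rows left after filtering")

    group_col = df[selection.group_key].astype(str)
    if selection.shown_groups is not None:
        wanted = [str(g) for g in selection.shown_groups]
    else:
        wanted = list(dict.fromkeys(group_col))
    out: Dict[str, np.ndarray] = {}
    n_dropped = 0
    for g in wanted:
        vals = pd.to_numeric(
            df.loc[group_col == g, selection.metric_name], errors="coerce"
        ).to_numpy(dtype=float)
        keep = ~np.isnan(vals)
        n_dropped += int((~keep).sum())
        out[g] = vals[keep]
    if n_dropped:
        logger.info("dropped %d NA %s value(s)", n_dropped, selection.metric_name)
    if all(v.size == 0 for v in out.values()):
        raise EmptySelectionError("all selected groups are empty")
    return out


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when both groups have at most
    :data:`EXACT_N_MAX` values and the pooled sample has no ties; otherwise
    the normal approximation with tie correction.  Returns (U statistic of
    ``group_a``, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX and not has_ties
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return (float(res.statistic), float(res.pvalue))


@dataclass
class GroupSummary:
    """Tukey five-number summary of one group."""

    group: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: List[float]


def boxplot_summary(
    groups: Dict[str, np.ndarray],
) -> Tuple[List[GroupSummary], Optional[float], Optional[str]]:
    """Boxplot statistics per group, with a rank-sum p for two groups.

    Whiskers follow the Tukey convention: the most extreme data point
    within 1.5 x IQR of the box; points beyond are listed as outliers.
    Returns (summaries, p_value, note); the p-value is computed only when
    exactly two non-empty groups are shown, otherwise ``note`` says why it
    was omitted.
    """
    summaries = []
    for name, vals in groups.items():
        v = np.sort(np.asarray(vals, dtype=float))
        if v.size == 0:
            summaries.append(GroupSummary(name, 0, *[math.nan] * 5, outliers=[]))
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        whisk_lo = float(inside.min()) if inside.size else float(med)
        whisk_hi = float(inside.max()) if inside.size else float(med)
        outliers = [float(x) for x in v[(v < lo_fence) | (v > hi_fence)]]
        summaries.append(
            GroupSummary(name, int(v.size), float(med), float(q1), float(q3),
                         whisk_lo, whisk_hi, outliers)
        )
    nonempty = [s.group for s in summaries if s.n > 0]
    if len(nonempty) == 2:
        _, p = rank_sum_test(groups[nonempty[0]], groups[nonempty[1]])
        return summaries, p, None
    note = (
        f"p-value omitted: {len(nonempty)} non-empty group(s) shown; "
        "pairwise comparison requires exactly 2"
    )
    return summaries, None, note
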