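"""Thin orchestration: input table -> GR values -> conditions -> fitted metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import pandas as pd

from . import fitting, gr, io


@dataclass
class AnalysisResult:
    series: List[io.ConditionSeries]
    results: List[fitting.ConditionResult]


def analyze(
    source,
    case: str,
    grouping_keys: Optional[Sequence[str]] = None,
    config: Optional[fitting.FitConfig] = None,
) -> AnalysisResult:
    """Run the full analysis on a path/buffer, DataFrame, or record list."""
    if isinstance(source, pd.DataFrame):
        records = io.records_from_frame(source, case)
    elif isinstance(source, (list, tuple)):
        records = list(source)
    else:
        records = io.read_input_table(source, case)
    available = list(records[0].metadata.keys())
    scheme = io.GroupingScheme.build(available, grouping_keys)
    gr_values, rel_counts = gr.compute_gr_table(records, case)
    series = io.group_conditions(records, scheme, gr_values, rel_counts)
    results = fitting.fit_conditions(series, config)
    return AnalysisResult(series=series, results=results)
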