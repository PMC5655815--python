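"""Experimental data model, tabular I/O, and grouping-variable semantics.

Input is a UTF-8 tab-separated table with one row per well.  Two layouts
(cases) are supported:

Case A (endpoint + time-zero counts)::

    concentration  cell_count  cell_count__ctrl  cell_count__time0  <metadata...>

Case C (endpoint counts + assay duration and untreated doubling time)::

    concentration  cell_count  cell_count__ctrl  treatment_duration  division_time  <metadata...>

Every other column is metadata (cell line, agent, replicate, ...).  A
*grouping scheme* selects which metadata columns define an experimental
condition; rows that agree on all grouping keys belong to one condition and
are averaged per concentration over the remaining (non-grouping) columns
before curve fitting.  ``concentration`` can never be a grouping key — it
is the independent variable of every dose-response curve.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CASE_A_REQUIRED = (
    "concentration",
    "cell_count",
    "cell_count__ctrl",
    "cell_count__time0",
)
CASE_C_REQUIRED = (
    "concentration",
    "cell_count",
    "cell_count__ctrl",
    "treatment_duration",
    "division_time",
)
# columns exclusive to the *other* case → ambiguity if present
_CASE_ONLY = {
    "A": ("cell_count__time0",),
    "C": ("treatment_duration", "division_time"),
}

POSITIVE_INF = "+Inf"
NEGATIVE_INF = "-Inf"
NA = "NA"


class InputFormatError(ValueError):
    """Missing/unparseable required column."""


class InputValidationError(ValueError):
    """Row-level value violates an invariant (e.g. non-positive count)."""


class AmbiguousCaseError(ValueError):
    """Table mixes Case A and Case C columns."""


@dataclass
class WellRecord:
    """One measured well: counts, concentration and free-form metadata."""

    concentration: float
    cell_count: float
    cell_count_ctrl: float
    cell_count_time0: Optional[float] = None
    treatment_duration: Optional[float] = None
    division_time: Optional[float] = None
    metadata: Dict[str, str] = field(default_factory=dict)


@dataclass
class GroupingScheme:
    """Partition of metadata columns into condition-defining and averaged keys."""

    grouping_keys: List[str]
    averaged_keys: List[str]

    @classmethod
    def build(cls, available: Sequence[str], grouping_keys: Optional[Sequence[str]] = None) -> "GroupingScheme":
        """Validate ``grouping_keys`` against the available metadata columns.

        By default every metadata column is a grouping key (no averaging).
        """
        available = list(available)
        if grouping_keys is None:
            grouping_keys = list(available)
        grouping_keys = list(grouping_keys)
        if "concentration" in grouping_keys:
            raise ValueError(
                "'concentration' cannot be a grouping variable; it is the "
                "independent variable of the dose-response curve"
            )
        unknown = [k for k in grouping_keys if k not in available]
        if unknown:
            raise ValueError(
                f"unknown grouping keys {unknown}; available metadata "
                f"columns: {available}"
            )
        averaged = [k for k in available if k not in grouping_keys]
        return cls(grouping_keys=grouping_keys, averaged_keys=averaged)


@dataclass
class ConditionSeries:
    """Per-condition dose-response points, averaged over replicates.

    ``points`` holds (concentration, mean GR, mean relative count,
    n replicates) tuples sorted by strictly increasing concentration.
    """

    condition_id: Tuple[str, ...]
    condition_keys: Tuple[str, ...]
    points: List[Tuple[float, float, float, int]]

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def gr_values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def relative_counts(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    @property
    def label(self) -> str:
        return " / ".join(str(v) for v in self.condition_id) or "all"


def _required_columns(case: str) -> Tuple[str, ...]:
    case = case.upper()
    if case == "A":
        return CASE_A_REQUIRED
    if case == "C":
        return CASE_C_REQUIRED
    raise ValueError(f"unknown case {case!r}; expected 'A' or 'C'")


def read_input_table(path_or_buffer, case: str) -> List[WellRecord]:
    """Parse a TSV input table into validated :class:`WellRecord` objects.

    Raises :class:`InputFormatError` naming the first missing required
    column, :class:`AmbiguousCaseError` if columns of the other case are
    present, and :class:`InputValidationError` (with 1-based data row
    number) for non-positive counts or concentrations.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str, encoding="utf-8")
    return records_from_frame(df, case)


def records_from_frame(df: pd.DataFrame, case: str) -> List[WellRecord]:
    """Validate an in-memory table (same contract as :func:`read_input_table`)."""
    case = case.upper()
    required = _required_columns(case)
    for col in required:
        if col not in df.columns:
            raise InputFormatError(f"missing required column '{col}'")
    foreign = [c for c in _CASE_ONLY["C" if case == "A" else "A"] if c in df.columns]
    if foreign:
        raise AmbiguousCaseError(
            f"table declared Case {case} but contains Case "
            f"{'C' if case == 'A' else 'A'} column(s) {foreign}; mixed-case "
            "datasets are rejected"
        )
    meta_cols = [c for c in df.columns if c not in required]

    records: List[WellRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        numeric = {}
        for col in required:
            raw = row[col]
            try:
                numeric[col] = float(raw)
            except (TypeError, ValueError):
                raise InputFormatError(
                    f"row {i}: column '{col}' value {raw!r} is not numeric"
                ) from None
            if not math.isfinite(numeric[col]) or numeric[col] <= 0:
                raise InputValidationError(
                    f"row {i}: column '{col}' must be strictly positive, "
                    f"got {raw!r}"
                )
        rec = WellRecord(
            concentration=numeric["concentration"],
            cell_count=numeric["cell_count"],
            cell_count_ctrl=numeric["cell_count__ctrl"],
            cell_count_time0=numeric.get("cell_count__time0"),
            treatment_duration=numeric.get("treatment_duration"),
            division_time=numeric.get("division_time"),
            metadata={c: str(row[c]) for c in meta_cols},
        )
        records.append(rec)
    if not records:
        raise InputValidationError("input table contains no data rows")
    return records


def records_to_frame(records: Sequence[WellRecord], case: str) -> pd.DataFrame:
    """Serialize records back to the tabular input layout (round-trippable)."""
    required = _required_columns(case.upper())
    field_of = {
        "concentration": "concentration",
        "cell_count": "cell_count",
        "cell_count__ctrl": "cell_count_ctrl",
        "cell_count__time0": "cell_count_time0",
        "treatment_duration": "treatment_duration",
        "division_time": "division_time",
    }
    meta_cols = list(records[0].metadata.keys())
    data = {col: [getattr(r, field_of[col]) for r in records] for col in required}
    for col in meta_cols:
        data[col] = [r.metadata[col] for r in records]
    return pd.DataFrame(data, columns=list(required) + meta_cols)


def group_conditions(
    records: Sequence[WellRecord],
    scheme: GroupingScheme,
    gr_values: Sequence[float],
    relative_counts: Sequence[float],
) -> List[ConditionSeries]:
    """Partition records into conditions and average replicates per concentration.

    One :class:`ConditionSeries` per unique grouping-key tuple; within a
    condition, rows sharing a concentration are collapsed by the arithmetic
    mean of their GR values and relative counts, with the replicate count
    recorded.  Output order follows first appearance in the input.
    """
    if len(records) == 0:
        raise ValueError("no records to group")
    if not (len(records) == len(gr_values) == len(relative_counts)):
        raise ValueError("records, gr_values and relative_counts must align")

    keys = tuple(scheme.grouping_keys)
    buckets: Dict[Tuple[str, ...], Dict[float, List[Tuple[float, float]]]] = {}
    order: List[Tuple[str, ...]] = []
    for rec, gr, rel in zip(records, gr_values, relative_counts):
        cid = tuple(str(rec.metadata[k]) for k in keys)
        if cid not in buckets:
            buckets[cid] = {}
            order.append(cid)
        buckets[cid].setdefault(rec.concentration, []).append((gr, rel))

    out: List[ConditionSeries] = []
    for cid in order:
        pts = []
        for conc in sorted(buckets[cid]):
            vals = buckets[cid][conc]
            grs = [v[0] for v in vals]
            rels = [v[1] for v in vals]
            pts.append((conc, float(np.mean(grs)), float(np.mean(rels)), len(vals)))
        out.append(ConditionSeries(condition_id=cid, condition_keys=keys, points=pts))
    return out


def _fmt(v) -> str:
    """Format a cell: floats at 10 significant digits, +/-Inf and NA literals."""
    if v is None:
        return NA
    if isinstance(v, (bool, np.bool_)):
        return "TRUE" if v else "FALSE"
    if isinstance(v, str):
        return v
    f = float(v)
    if math.isnan(f):
        return NA
    if math.isinf(f):
        return POSITIVE_INF if f > 0 else NEGATIVE_INF
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return format(f, ".10g")


def _write_tsv(df: pd.DataFrame, path_or_buffer) -> None:
    formatted = df.map(_fmt)
    formatted.to_csv(path_or_buffer, sep="\t", index=False)


def write_gr_values_table(series_list: Sequence[ConditionSeries], path) -> None:
    """Write the per-point table: grouping keys, concentration, GR, relative count, n."""
    rows = []
    for s in series_list:
        for conc, gr, rel, n in s.points:
            row = dict(zip(s.condition_keys, s.condition_id))
            row.update(
                concentration=conc, GR_value=gr, relative_count=rel, n_replicates=n
            )
            rows.append(row)
    _write_tsv(pd.DataFrame(rows), path)


#: column order of the per-condition metrics table (after the grouping keys)
METRIC_COLUMNS = [
    "GRinf", "GEC50", "log10_GEC50", "hGR", "GR50", "GRmax", "GRAOC",
    "gr_flat_fit", "gr_f_stat", "gr_f_pvalue", "gr_rss", "gr_response_class",
    "Einf", "EC50", "h", "IC50", "Emax", "AUC",
    "trad_flat_fit", "trad_f_stat", "trad_f_pvalue", "trad_rss",
]


def write_metrics_table(results: Sequence, path) -> None:
    """Write one row per fitted condition (see :data:`METRIC_COLUMNS`).

    ``results`` is a sequence of :class:`grdose.fitting.ConditionResult`.
    Infinite metrics serialize as ``+Inf``/``-Inf`` and missing ones as
    ``NA``; the table round-trips through :func:`read_metrics_table`.
    """
    rows = []
    for res in results:
        g, t = res.gr_fit, res.trad_fit
        row = dict(zip(res.series.condition_keys, res.series.condition_id))
        row.update(
            GRinf=g.gr_inf, GEC50=g.gec50,
            log10_GEC50=(math.log10(g.gec50) if g.gec50 and not math.isnan(g.gec50) else float("nan")),
            hGR=g.h_gr, GR50=g.gr50, GRmax=g.gr_max, GRAOC=g.gr_aoc,
            gr_flat_fit=g.flat_fit, gr_f_stat=g.f_stat, gr_f_pvalue=g.f_pvalue,
            gr_rss=g.rss, gr_response_class=g.response_class,
            Einf=t.e_inf, EC50=t.ec50, h=t.h, IC50=t.ic50, Emax=t.e_max,
            AUC=t.auc, trad_flat_fit=t.flat_fit, trad_f_stat=t.f_stat,
            trad_f_pvalue=t.f_pvalue, trad_rss=t.rss,
        )
        rows.append(row)
    _write_tsv(pd.DataFrame(rows), path)


def read_metrics_table(path_or_buffer) -> pd.DataFrame:
    """Read a metrics table back, decoding +/-Inf, NA and TRUE/FALSE literals."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str, keep_default_na=False)
    decoded = {}
    for col in df.columns:
        s = df[col]
        if col in METRIC_COLUMNS:
            if col.endswith("flat_fit"):
                decoded[col] = s.map({"TRUE": True, "FALSE": False})
            elif col.endswith("response_class"):
                decoded[col] = s.replace(NA, None)
            else:
                special = {NA: math.nan, POSITIVE_INF: math.inf,
                           NEGATIVE_INF: -math.inf}
                decoded[col] = s.map(lambda v: special.get(v, None))
                numeric = s[~s.isin(special)]
                decoded[col].update(pd.to_numeric(numeric))
                decoded[col] = decoded[col].astype(float)
        else:
            decoded[col] = s
    return pd.DataFrame(decoded, columns=df.columns)
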