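"""Normalized growth-rate inhibition (GR) values from cell counts.

The GR value quantifies drug effect on a per-division basis,

    GR(c) = 2**(k(c)/k(0)) - 1,

where ``k(c)`` is the growth rate of treated cells and ``k(0)`` the growth
rate of untreated (vehicle) controls.  GR = 1 means no effect, GR = 0
complete cytostasis, and negative values (bounded below by -1) net cell
death.  Unlike relative cell count, GR is independent of how many divisions
the control population undergoes during the assay, which removes the
division-rate confound from downstream potency/efficacy metrics.

Two endpoint estimators are provided:

* :func:`gr_fixed_difference` -- from a time-zero count ``x0``, an endpoint
  control count ``x_ctrl`` and an endpoint treated count ``x_treated``;
* :func:`gr_division_time` -- from the endpoint treated/control ratio plus
  the assay duration ``T`` and the untreated doubling time ``Td``.

Both reduce to the rate-ratio definition and agree exactly whenever the
control actually grew at the stated doubling time, i.e.
``x_ctrl = x0 * 2**(T/Td)``.

All functions accept scalars or numpy arrays (broadcasting applies) and
raise :class:`GRDomainError` on inputs outside the model's domain rather
than returning NaN.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np


class GRDomainError(ValueError):
    """Input outside the domain of the GR formulas (e.g. shrinking control)."""


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise GRDomainError("non-finite input")
    return a


def gr_from_rates(k_treated, k_control):
    """GR value from growth rates: ``2**(k_treated/k_control) - 1``.

    ``k_control`` must be strictly positive — the method presumes a
    proliferating control population.
    """
    kt = _as_array(k_treated)
    kc = _as_array(k_control)
    if np.any(kc <= 0):
        raise GRDomainError("control growth rate must be positive")
    out = np.exp2(kt / kc) - 1.0
    return out if out.ndim else float(out)


def gr_fixed_difference(x0, x_ctrl, x_treated):
    """GR value by the fixed-difference estimator.

    ``2**( log2(x_treated/x0) / log2(x_ctrl/x0) ) - 1`` with ``x0`` the
    count at treatment start and ``x_ctrl``/``x_treated`` the endpoint
    counts of control and treated wells.  Requires all counts positive and
    ``x_ctrl > x0`` (the control must have grown).
    """
    x0 = _as_array(x0)
    xc = _as_array(x_ctrl)
    xt = _as_array(x_treated)
    if np.any(x0 <= 0) or np.any(xc <= 0) or np.any(xt <= 0):
        raise GRDomainError("cell counts must be strictly positive")
    if np.any(xc <= x0):
        raise GRDomainError("control did not grow (x_ctrl <= x0)")
    out = np.exp2(np.log2(xt / x0) / np.log2(xc / x0)) - 1.0
    return out if out.ndim else float(out)


def gr_division_time(x_ratio, T, Td):
    """GR value from the treated/control ratio and the untreated doubling time.

    ``2**( (log2(x_ratio) + T/Td) / (T/Td) ) - 1`` where ``x_ratio`` is
    x(c)/x(0), ``T`` the assay duration and ``Td`` the untreated doubling
    time in the same units.
    """
    r = _as_array(x_ratio)
    T = _as_array(T)
    Td = _as_array(Td)
    if np.any(r <= 0):
        raise GRDomainError("count ratio must be strictly positive")
    if np.any(T <= 0) or np.any(Td <= 0):
        raise GRDomainError("durations must be strictly positive")
    n_div = T / Td  # doublings of the untreated population
    out = np.exp2((np.log2(r) + n_div) / n_div) - 1.0
    return out if out.ndim else float(out)


def relative_count(x_treated, x_ctrl):
    """Relative cell count x(c)/x(0) — the basis of traditional metrics."""
    xt = _as_array(x_treated)
    xc = _as_array(x_ctrl)
    if np.any(xt <= 0) or np.any(xc <= 0):
        raise GRDomainError("cell counts must be strictly positive")
    out = xt / xc
    return out if out.ndim else float(out)


def compute_gr_table(records: Sequence, case: str) -> Tuple[np.ndarray, np.ndarray]:
    """GR values and relative counts for a list of well records.

    Parameters
    ----------
    records
        Sequence of :class:`grdose.io.WellRecord`.
    case
        ``"A"`` (time-zero counts available, fixed-difference estimator) or
        ``"C"`` (assay duration + doubling time, division-time estimator).

    Returns
    -------
    (gr_values, relative_counts)
        Two float arrays aligned with ``records``.
    """
    case = case.upper()
    if case not in ("A", "C"):
        raise ValueError(f"unknown case {case!r}; expected 'A' or 'C'")
    n = len(records)
    gr = np.empty(n)
    rel = np.empty(n)
    for i, rec in enumerate(records):
        rel[i] = relative_count(rec.cell_count, rec.cell_count_ctrl)
        if case == "A":
            gr[i] = gr_fixed_difference(
                rec.cell_count_time0, rec.cell_count_ctrl, rec.cell_count
            )
        else:
            gr[i] = gr_division_time(
                rel[i], rec.treatment_duration, rec.division_time
            )
    return gr, rel
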