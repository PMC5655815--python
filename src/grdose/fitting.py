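"""Sigmoidal dose-response fitting and sensitivity metrics.

Per experimental condition, both the GR values and the relative cell counts
are fitted to a 3-parameter logistic with the upper asymptote pinned at 1
(the untreated condition defines y = 1 by construction of both response
scales):

    y(c) = y_inf + (1 - y_inf) / (1 + (c / c50)**h)

The fit is a bounded nonlinear least-squares problem in log10
concentration, solved from a deterministic multi-start grid (c50 at each
tested concentration, h in {1, 2}, y_inf at the smallest observed
response); the best residual sum of squares wins.  Significance of the
sigmoid against a flat line is assessed with the nested-model F-test; a
non-significant fit (p >= alpha), non-convergence, or fewer than 4 distinct
concentrations triggers the flat-line fallback, whose metrics are set to
documented defaults rather than extrapolated from an unreliable curve.

Metrics on the GR scale: GR50 (fitted curve crosses 0.5), GEC50
(inflection), GRinf (lower asymptote), hGR (steepness), GRmax (lowest
measured GR at the two highest tested concentrations), GRAOC (trapezoidal
area between the measured GR points and 1 over log10 concentration,
normalized by the tested log10 range).  The traditional metrics IC50, EC50,
Einf, h, Emax and AUC are the mirror quantities on the relative-count
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .io import ConditionSeries

__all__ = [
    "FitConfig", "LogisticFit", "GRCurveFit", "TraditionalCurveFit",
    "ConditionResult", "fit_logistic", "f_test_flat", "fit_condition_gr",
    "fit_condition_traditional", "fit_conditions", "gr50_from_params",
    "max_effect", "area_metric", "cap_concentration_metric",
    "classify_response", "logistic",
]


@dataclass
class FitConfig:
    """Tunable fitting options.

    alpha
        F-test significance level for keeping the sigmoid over the flat
        line (default 0.05).
    h_bounds
        Bounds on the Hill coefficient (default (0.1, 5)).
    c50_bound_factor
        c50 is constrained to [min_conc / factor, max_conc * factor]
        (default 100).
    cap
        Optional concentration cap applied to GR50/IC50 (e.g. the highest
        tested concentration, or 31 for micromolar tables); ``None``
        disables capping.
    aoc_normalization
        "range" divides the trapezoidal area by the tested log10 range so
        datasets spanning different ranges are comparable; "none" leaves
        the raw integral.
    gr_inf_bounds / e_inf_bounds
        Lower-asymptote bounds on the GR and relative-count scales.
    """

    alpha: float = 0.05
    h_bounds: Tuple[float, float] = (0.1, 5.0)
    c50_bound_factor: float = 100.0
    cap: Optional[float] = None
    aoc_normalization: str = "range"
    gr_inf_bounds: Tuple[float, float] = (-1.0, 1.0)
    e_inf_bounds: Tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.aoc_normalization not in ("range", "none"):
            raise ValueError("aoc_normalization must be 'range' or 'none'")


def logistic(conc, y_inf: float, c50: float, h: float):
    """Evaluate the 3-parameter logistic (upper asymptote 1)."""
    conc = np.asarray(conc, dtype=float)
    return y_inf + (1.0 - y_inf) / (1.0 + (conc / c50) ** h)


@dataclass
class LogisticFit:
    y_inf: float
    c50: float
    h: float
    rss: float
    converged: bool


def fit_logistic(
    concentrations: Sequence[float],
    responses: Sequence[float],
    floor_bounds: Tuple[float, float] = (-1.0, 1.0),
    h_bounds: Tuple[float, float] = (0.1, 5.0),
    c50_bound_factor: float = 100.0,
) -> LogisticFit:
    """Bounded multi-start least-squares fit of the 3-parameter logistic.

    Fitting is done in log10 concentration.  The start grid (c50 at each
    tested concentration crossed with h in {1, 2}) is deterministic, so
    identical inputs always give identical fits.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.ndim != 1 or conc.shape != resp.shape or conc.size < 1:
        raise ValueError("need matched 1-d concentration/response arrays")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    logc = np.log10(conc)
    lo = np.log10(conc.min() / c50_bound_factor)
    hi = np.log10(conc.max() * c50_bound_factor)
    lower = np.array([floor_bounds[0], lo, h_bounds[0]])
    upper = np.array([floor_bounds[1], hi, h_bounds[1]])

    def residuals(theta):
        y_inf, lc50, h = theta
        y = y_inf + (1.0 - y_inf) / (1.0 + 10.0 ** (h * (logc - lc50)))
        return y - resp

    _LN10 = math.log(10.0)

    def jacobian(theta):
        y_inf, lc50, h = theta
        u = 10.0 ** (h * (logc - lc50))
        denom = (1.0 + u) ** 2
        d_yinf = 1.0 - 1.0 / (1.0 + u)
        d_lc50 = (1.0 - y_inf) * u * h * _LN10 / denom
        d_h = -(1.0 - y_inf) * u * (logc - lc50) * _LN10 / denom
        return np.stack([d_yinf, d_lc50, d_h], axis=1)

    y0 = float(np.clip(resp.min(), *floor_bounds))
    best: Optional[LogisticFit] = None
    for lc50_0 in np.unique(logc):
        for h0 in (1.0, 2.0):
            x0 = np.clip(np.array([y0, lc50_0, h0]), lower + 1e-9, upper - 1e-9)
            try:
                sol = optimize.least_squares(
                    residuals, x0, jac=jacobian, bounds=(lower, upper),
                    method="trf", max_nfev=60,
                )
            except Exception:
                continue
            if sol.status < 0:  # infeasible; status 0 (iteration cap) is usable
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best.rss:
                best = LogisticFit(
                    y_inf=float(sol.x[0]),
                    c50=float(10.0 ** sol.x[1]),
                    h=float(sol.x[2]),
                    rss=rss,
                    converged=True,
                )
    if best is None:
        flat = float(np.mean(resp))
        return LogisticFit(
            y_inf=flat, c50=math.nan, h=math.nan,
            rss=float(np.sum((resp - flat) ** 2)), converged=False,
        )
    return best


def f_test_flat(
    responses: Sequence[float], sigmoid_rss: float, n_sigmoid_params: int = 3
) -> Tuple[float, float]:
    """Nested-model F-test of the sigmoid against the flat (mean) line.

    F = ((RSS_flat - RSS_sig) / (df_flat - df_sig)) / (RSS_sig / df_sig)
    with df_flat = n - 1 and df_sig = n - n_sigmoid_params; the p-value is
    the survival function of F(df_flat - df_sig, df_sig).  Undefined
    (NaN, NaN) when n <= n_sigmoid_params; p = 0 by convention when the
    sigmoid residual is exactly zero with positive flat residual.
    """
    resp = np.asarray(responses, dtype=float)
    n = resp.size
    df_sig = n - n_sigmoid_params
    df_diff = n_sigmoid_params - 1
    if df_sig < 1:
        return (math.nan, math.nan)
    rss_flat = float(np.sum((resp - resp.mean()) ** 2))
    if sigmoid_rss <= 0:
        if rss_flat <= 0:
            return (0.0, 1.0)
        return (math.inf, 0.0)
    f = max((rss_flat - sigmoid_rss) / df_diff, 0.0) / (sigmoid_rss / df_sig)
    p = float(stats.f.sf(f, df_diff, df_sig))
    return (float(f), p)


def gr50_from_params(gr_inf: float, gec50: float, h_gr: float) -> float:
    """Concentration at which the fitted curve crosses 0.5 (closed form).

    ``+inf`` when the lower asymptote is at or above 0.5 — the curve never
    reaches half-inhibition within any concentration.  Same formula serves
    IC50 on the relative-count scale.
    """
    if math.isnan(gr_inf) or math.isnan(gec50) or math.isnan(h_gr):
        return math.nan
    if gr_inf >= 0.5:
        return math.inf
    ratio = (1.0 - gr_inf) / (0.5 - gr_inf) - 1.0
    return gec50 * ratio ** (1.0 / h_gr)


def max_effect(points: Sequence[Tuple[float, float]], k: int = 2) -> float:
    """Lowest response among the ``k`` highest tested concentrations.

    On the GR scale this is GRmax; on the relative-count scale, Emax.
    Uses the per-concentration averaged measurements, not the fitted curve.
    """
    if len(points) == 0:
        raise ValueError("need at least one point")
    top = sorted(points, key=lambda p: p[0])[-min(k, len(points)):]
    return float(min(p[1] for p in top))


def area_metric(
    points: Sequence[Tuple[float, float]],
    mode: str,
    normalization: str = "range",
) -> float:
    """Trapezoidal area metric over log10 concentration.

    mode "gr_aoc": area *over* the curve, i.e. integral of (1 - response) —
    used for GR values, which can dip below zero.  mode "trad_auc": area
    *under* the curve, integral of the response — used for relative counts.
    With ``normalization="range"`` the integral is divided by the log10
    concentration range, making values from different tested ranges
    comparable (and dimensionless: 0 = no effect, 1 = full effect for
    gr_aoc).  Returns NaN for a single point.
    """
    if mode not in ("gr_aoc", "trad_auc"):
        raise ValueError("mode must be 'gr_aoc' or 'trad_auc'")
    pts = sorted(points, key=lambda p: p[0])
    if len(pts) < 2:
        return math.nan
    x = np.log10([p[0] for p in pts])
    y = np.array([p[1] for p in pts], dtype=float)
    integrand = 1.0 - y if mode == "gr_aoc" else y
    area = float(np.trapezoid(integrand, x))
    if normalization == "range":
        area /= float(x[-1] - x[0])
    return area


def cap_concentration_metric(value: float, cap: Optional[float]) -> float:
    """Cap a concentration metric (GR50/IC50); +inf maps to the cap."""
    if cap is None or math.isnan(value):
        return value
    return min(value, cap)


def classify_response(gr_inf: float, tol: float = 0.05) -> Optional[str]:
    """Classify a drug by the sign of GRinf.

    GRinf within ``tol`` of zero → "cytostatic" (growth fully arrested but
    no net death), positive → "partially_cytostatic", negative →
    "cytotoxic" (net cell death at saturating dose).
    """
    if gr_inf is None or math.isnan(gr_inf):
        return None
    if abs(gr_inf) <= tol:
        return "cytostatic"
    return "partially_cytostatic" if gr_inf > 0 else "cytotoxic"


@dataclass
class GRCurveFit:
    """Fitted GR dose-response curve and derived metrics for one condition."""

    gr_inf: float
    gec50: float
    h_gr: float
    flat_fit: bool
    flat_level: float
    f_stat: float
    f_pvalue: float
    rss: float
    gr50: float
    gr_max: float
    gr_aoc: float
    response_class: Optional[str] = None


@dataclass
class TraditionalCurveFit:
    """Relative-count mirror of :class:`GRCurveFit`."""

    e_inf: float
    ec50: float
    h: float
    flat_fit: bool
    flat_level: float
    f_stat: float
    f_pvalue: float
    rss: float
    ic50: float
    e_max: float
    auc: float


@dataclass
class ConditionResult:
    series: ConditionSeries
    gr_fit: GRCurveFit
    trad_fit: TraditionalCurveFit


def _fit_response_curve(conc, resp, floor_bounds, config: FitConfig):
    """Shared fit + F-test + flat-fallback machinery for both scales.

    Returns (y_inf, c50, h, flat, flat_level, f_stat, f_pvalue, rss, y50)
    where y50 is the 0.5-crossing concentration of the fitted curve.
    """
    n_distinct = np.unique(conc).size
    fit = fit_logistic(
        conc, resp,
        floor_bounds=floor_bounds,
        h_bounds=config.h_bounds,
        c50_bound_factor=config.c50_bound_factor,
    )
    f_stat, f_pvalue = f_test_flat(resp, fit.rss)
    flat = (
        not fit.converged
        or n_distinct < 4
        or math.isnan(f_pvalue)
        or f_pvalue >= config.alpha
    )
    flat_level = float(np.mean(resp))
    if flat:
        rss = float(np.sum((resp - flat_level) ** 2))
        # crossing unidentifiable below the tested range when the flat level
        # already sits at/under 0.5; "never reached" (+inf) when above
        y50 = math.inf if flat_level > 0.5 else math.nan
        return (flat_level, math.nan, math.nan, True, flat_level,
                f_stat, f_pvalue, rss, y50)
    y50 = gr50_from_params(fit.y_inf, fit.c50, fit.h)
    return (fit.y_inf, fit.c50, fit.h, False, flat_level,
            f_stat, f_pvalue, fit.rss, y50)


def fit_condition_gr(series: ConditionSeries, config: Optional[FitConfig] = None) -> GRCurveFit:
    """Fit the GR curve of one condition and derive all GR metrics."""
    config = config or FitConfig()
    conc = series.concentrations
    resp = series.gr_values
    (gr_inf, gec50, h_gr, flat, flat_level, f_stat, f_pvalue, rss,
     gr50) = _fit_response_curve(conc, resp, config.gr_inf_bounds, config)
    pts = list(zip(conc, resp))
    return GRCurveFit(
        gr_inf=gr_inf, gec50=gec50, h_gr=h_gr, flat_fit=flat,
        flat_level=flat_level, f_stat=f_stat, f_pvalue=f_pvalue, rss=rss,
        gr50=cap_concentration_metric(gr50, config.cap),
        gr_max=max_effect(pts),
        gr_aoc=area_metric(pts, "gr_aoc", config.aoc_normalization),
        response_class=classify_response(gr_inf),
    )


def fit_condition_traditional(
    series: ConditionSeries, config: Optional[FitConfig] = None
) -> TraditionalCurveFit:
    """Fit the relative-count curve and derive the traditional metrics."""
    config = config or FitConfig()
    conc = series.concentrations
    resp = series.relative_counts
    (e_inf, ec50, h, flat, flat_level, f_stat, f_pvalue, rss,
     ic50) = _fit_response_curve(conc, resp, config.e_inf_bounds, config)
    pts = list(zip(conc, resp))
    return TraditionalCurveFit(
        e_inf=e_inf, ec50=ec50, h=h, flat_fit=flat, flat_level=flat_level,
        f_stat=f_stat, f_pvalue=f_pvalue, rss=rss,
        ic50=cap_concentration_metric(ic50, config.cap),
        e_max=max_effect(pts),
        auc=area_metric(pts, "trad_auc", config.aoc_normalization),
    )


def fit_conditions(
    series_list: Sequence[ConditionSeries], config: Optional[FitConfig] = None
) -> List[ConditionResult]:
    """Fit GR and traditional curves for every condition."""
    config = config or FitConfig()
    return [
        ConditionResult(
            series=s,
            gr_fit=fit_condition_gr(s, config),
            trad_fit=fit_condition_traditional(s, config),
        )
        for s in series_list
    ]
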