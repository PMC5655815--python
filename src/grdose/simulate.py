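"""Forward simulation of drug-treated cell growth and synthetic datasets.

The prototypical dose-response model: untreated cells double every ``Td``
days, and drug reduces the growth rate through a Hill term,

    k(c) = (1/Td) * (1 - SCmax * c**h / (SC50**h + c**h))        [doublings/day]

so ``SC50`` is the concentration of half-maximal model effect, ``h`` its
steepness, and ``SCmax`` the maximal fractional effect on the growth rate:
SCmax = 1 stops growth entirely at saturating dose (cytostatic), SCmax < 1
only slows it (partially cytostatic), and SCmax > 1 drives the net rate
negative (cytotoxic).  Populations grow exponentially,
``x(c, t) = x0 * 2**(k(c) * t)``.

Under this model the GR curve ``2**(k(c)/k(0)) - 1`` depends only on SC50,
SCmax and h — not on the division time — whereas the relative-count curve
``2**((k(c) - k(0)) * T)`` and hence IC50/Emax/AUC shift with ``Td`` and the
assay duration ``T``.  That division-rate confound is exactly what GR
metrics remove, and the simulator exists to demonstrate it and to generate
test datasets.

:func:`generate_dataset` emits complete input tables (Case A or C) for a
factorial design of cell lines x agents x concentrations x replicates, with
optional multiplicative lognormal count noise; identical seed and design
give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import gr as _gr

__all__ = [
    "GrowthModelParams", "NoiseModel", "CellLineSpec", "AgentSpec",
    "SimulationDesign", "growth_rate", "simulate_counts", "model_gr_curve",
    "model_relative_count_curve", "preset", "PRESET_NAMES",
    "generate_dataset", "default_concentrations",
]


@dataclass
class GrowthModelParams:
    """Parameters of the prototypical growth model.

    td: untreated doubling time, days.  sc50: half-effect concentration.
    sc_max: maximal fractional effect on growth rate (>1 is cytotoxic).
    h: Hill coefficient of the drug-effect term.  x0: initial cell count.
    duration: assay length T, days.
    """

    td: float = 1.0
    sc50: float = 0.1
    sc_max: float = 1.0
    h: float = 2.0
    x0: float = 1000.0
    duration: float = 3.0

    def __post_init__(self):
        if self.td <= 0 or self.sc50 <= 0 or self.h <= 0:
            raise ValueError("td, sc50 and h must be positive")
        if self.sc_max < 0:
            raise ValueError("sc_max must be non-negative")
        if self.x0 <= 0 or self.duration <= 0:
            raise ValueError("x0 and duration must be positive")


@dataclass
class NoiseModel:
    """Multiplicative lognormal noise on simulated counts.

    ``count_cv`` is the coefficient of variation of the noise factor; the
    factor has mean 1 so noise does not bias counts.  cv = 0 disables noise.
    """

    count_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.count_cv < 0:
            raise ValueError("count_cv must be non-negative")

    def sigma(self) -> float:
        return math.sqrt(math.log1p(self.count_cv ** 2))


# typical presets: shared pharmacology, differing only in maximal effect
_PRESET_SCMAX = {
    "cytostatic": 1.0,          # growth fully arrested at saturating dose
    "partial_cytostatic": 0.5,  # growth halved
    "cytotoxic": 2.0,           # net death at saturating dose
}
PRESET_NAMES = tuple(_PRESET_SCMAX)


def preset(name: str) -> GrowthModelParams:
    """Typical cytostatic / partially cytostatic / cytotoxic parameter sets."""
    if name not in _PRESET_SCMAX:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return GrowthModelParams(sc_max=_PRESET_SCMAX[name])


def growth_rate(c, params: GrowthModelParams):
    """Growth rate k(c) in doublings/day; k(0) = 1/Td, k(inf) = (1-SCmax)/Td."""
    c = np.asarray(c, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    effect = np.zeros_like(c)
    pos = c > 0
    effect[pos] = params.sc_max * c[pos] ** params.h / (
        params.sc50 ** params.h + c[pos] ** params.h
    )
    out = (1.0 - effect) / params.td
    return float(out[0]) if scalar else out


def simulate_counts(
    params: GrowthModelParams,
    concentrations: Sequence[float],
    timepoints: Sequence[float],
) -> pd.DataFrame:
    """Deterministic exponential trajectories x0 * 2**(k(c) * t).

    Returns a tidy frame with columns concentration, time, cell_count.
    """
    conc = np.asarray(concentrations, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    k = np.atleast_1d(growth_rate(conc, params))
    counts = params.x0 * np.exp2(np.outer(k, t))
    rows = []
    for i, c in enumerate(conc):
        for j, tt in enumerate(t):
            rows.append({"concentration": c, "time": tt, "cell_count": counts[i, j]})
    return pd.DataFrame(rows)


def model_gr_curve(params: GrowthModelParams, concentrations) -> np.ndarray:
    """Analytic GR curve of the model; independent of td by construction."""
    k = np.atleast_1d(growth_rate(concentrations, params))
    k0 = growth_rate(0.0, params)
    return np.asarray(_gr.gr_from_rates(k, k0))


def model_relative_count_curve(params: GrowthModelParams, concentrations) -> np.ndarray:
    """Analytic endpoint relative-count curve 2**((k(c) - k(0)) * T)."""
    k = np.atleast_1d(growth_rate(concentrations, params))
    k0 = growth_rate(0.0, params)
    return np.exp2((k - k0) * params.duration)


def default_concentrations(n: int = 9, lo: float = 1e-3, hi: float = 10.0) -> np.ndarray:
    """Log-spaced dose range typical of a 9-point titration (1 nM - 10 uM)."""
    return np.logspace(math.log10(lo), math.log10(hi), n)


@dataclass
class CellLineSpec:
    name: str
    division_time: float  # days


@dataclass
class AgentSpec:
    name: str
    sc50: float
    sc_max: float = 1.0
    h: float = 2.0


@dataclass
class SimulationDesign:
    """Factorial design: every cell line x agent x concentration x replicate."""

    cell_lines: List[CellLineSpec]
    agents: List[AgentSpec]
    concentrations: List[float] = field(
        default_factory=lambda: list(default_concentrations())
    )
    replicates: int = 3
    x0: float = 1000.0
    duration: float = 3.0  # days

    @classmethod
    def from_dict(cls, d: Dict) -> "SimulationDesign":
        """Build from a plain mapping (e.g. parsed design YAML)."""
        kwargs = dict(d)
        kwargs["cell_lines"] = [CellLineSpec(**c) for c in d["cell_lines"]]
        kwargs["agents"] = [AgentSpec(**a) for a in d["agents"]]
        return cls(**kwargs)


def generate_dataset(
    design: SimulationDesign,
    noise: Optional[NoiseModel] = None,
    case: str = "A",
) -> pd.DataFrame:
    """Simulate a complete input table for the design.

    One treated row per (cell line, agent, replicate, concentration).  Each
    (cell line, agent, replicate) stratum shares one control well and one
    time-zero measurement — as on a real plate — whose noisy counts are
    copied onto every row of the stratum; treated counts get independent
    noise.  Case A rows carry cell_count__time0; Case C rows carry
    treatment_duration and division_time instead.
    """
    case = case.upper()
    if case not in ("A", "C"):
        raise ValueError("case must be 'A' or 'C'")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma()

    def jitter(n=None):
        if sigma == 0:
            return 1.0 if n is None else np.ones(n)
        return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n)

    conc = np.asarray(design.concentrations, dtype=float)
    rows = []
    for line in design.cell_lines:
        for agent in design.agents:
            params = GrowthModelParams(
                td=line.division_time, sc50=agent.sc50, sc_max=agent.sc_max,
                h=agent.h, x0=design.x0, duration=design.duration,
            )
            k = np.atleast_1d(growth_rate(conc, params))
            k0 = growth_rate(0.0, params)
            x_treated_true = design.x0 * np.exp2(k * design.duration)
            x_ctrl_true = design.x0 * np.exp2(k0 * design.duration)
            for rep in range(1, design.replicates + 1):
                x_time0 = design.x0 * jitter()
                x_ctrl = x_ctrl_true * jitter()
                x_treated = x_treated_true * jitter(conc.size)
                for c, xt in zip(conc, x_treated):
                    row = {
                        "concentration": c,
                        "cell_count": xt,
                        "cell_count__ctrl": x_ctrl,
                    }
                    if case == "A":
                        row["cell_count__time0"] = x_time0
                    else:
                        row["treatment_duration"] = design.duration
                        row["division_time"] = line.division_time
                    row.update(
                        cell_line=line.name, agent=agent.name, replicate=str(rep)
                    )
                    rows.append(row)
    return pd.DataFrame(rows)
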