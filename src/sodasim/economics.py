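"""Costing, QALY accrual, discounting, perspectives, and the ICER.

Costs and QALYs accrue per state-occupancy cycle from the simulation trace,
discounted at the configured annual rate (year 0 undiscounted), and are
rescaled from the simulated cohort to the California adult population.  Two
perspectives are evaluated:

* health care: direct medical costs only;
* government: health care costs plus tax administration costs minus soda tax
  revenue (net cost = ΔHC + admin − revenue).

Revenue and administration flows are annual annuities over the horizon,
discounted at the same rate as all other flows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import Trace
from .parameters import DrawnParameters, ModelConfig
from .states import HealthState, N_STATES


def discount(value: float, year_index: int, rate: float) -> float:
    """Present value of a flow occurring in cycle ``year_index`` (year 0 undiscounted)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if year_index < 0:
        raise ValueError("year_index must be >= 0")
    return value / (1.0 + rate) ** year_index


def annuity_factor(horizon: int, rate: float) -> float:
    """Sum of discount factors over cycles 0..horizon-1."""
    return sum((1.0 + rate) ** (-t) for t in range(horizon))


def _schedule_array(schedule: Mapping[HealthState, float], label: str) -> np.ndarray:
    arr = np.full(N_STATES, np.nan)
    for s, v in schedule.items():
        arr[int(s)] = v
    if np.isnan(arr).any():
        missing = [HealthState(i).name.lower() for i in np.flatnonzero(np.isnan(arr))]
        raise KeyError(f"{label} schedule missing states: {missing}")
    return arr


def accrue(trace: Trace, costs: Mapping[HealthState, float],
           utils: Mapping[HealthState, float], rate: float) -> tuple[float, float]:
    """Discounted (total cost, total QALYs) over all cycles and individuals.

    total = Σ_t Σ_s count(t, s) · schedule(s) · (1 + rate)^(−t); the death
    state carries zero cost and zero utility.
    """
    cost_arr = _schedule_array(costs, "cost")
    util_arr = _schedule_array(utils, "utility")
    dfs = (1.0 + rate) ** (-np.arange(trace.horizon))
    total_cost = float(dfs @ (trace.state_counts @ cost_arr))
    total_qaly = float(dfs @ (trace.state_counts @ util_arr))
    return total_cost, total_qaly


def revenue_stream(annual_revenue: float, admin_fraction: float,
                   horizon: int, rate: float) -> tuple[float, float]:
    """Discounted totals of the tax revenue and administration-cost annuities."""
    if not 0.0 <= admin_fraction <= 1.0:
        raise ValueError("admin_fraction must lie in [0, 1]")
    af = annuity_factor(horizon, rate)
    return annual_revenue * af, annual_revenue * admin_fraction * af


def rescale(value: float, factor: float) -> float:
    """Scale a model count or dollar amount up to the target population."""
    if factor <= 0:
        raise ValueError("rescale factor must be > 0")
    return value * factor


@dataclass(frozen=True)
class ICER:
    """An incremental cost-effectiveness ratio with its qualitative label.

    ``label`` is "standard" (positive trade-off), "dominant" (cheaper and
    more effective), "dominated" (costlier and less effective), or
    "undefined" when the QALY increment is zero (value is NaN).
    """

    value: float
    label: str

    @property
    def is_dominant(self) -> bool:
        return self.label == "dominant"


def icer(cost_tax: float, cost_sq: float, qaly_tax: float, qaly_sq: float) -> ICER:
    """ICER of the tax arm vs. status quo: Δnet cost / Δnet effectiveness."""
    d_cost = cost_tax - cost_sq
    d_qaly = qaly_tax - qaly_sq
    if d_qaly == 0.0:
        return ICER(math.nan, "undefined")
    if d_cost < 0.0 and d_qaly > 0.0:
        label = "dominant"
    elif d_cost > 0.0 and d_qaly < 0.0:
        label = "dominated"
    else:
        label = "standard"
    return ICER(d_cost / d_qaly, label)


@dataclass(frozen=True)
class CEAResult:
    """Population-rescaled cost-effectiveness summary for one parameter draw."""

    cost_sq: float
    cost_tax: float
    qaly_sq: float
    qaly_tax: float
    delta_cost_healthcare: float
    delta_qaly: float
    revenue_total: float
    admin_cost_total: float
    delta_cost_government: float
    icer_healthcare: ICER
    icer_government: ICER
    nmb_healthcare: float
    nmb_government: float
    saving_per_person_per_year: float
    wtp: float
    rescale_factor: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_qalys_billion", self.qaly_sq / 1e9, self.qaly_tax / 1e9),
            ("total_healthcare_cost_billion_usd", self.cost_sq / 1e9, self.cost_tax / 1e9),
            ("policy_implementation_cost_billion_usd", 0.0, self.admin_cost_total / 1e9),
            ("total_tax_revenue_billion_usd", 0.0, self.revenue_total / 1e9),
            ("net_cost_healthcare_billion_usd", None, self.delta_cost_healthcare / 1e9),
            ("net_cost_government_billion_usd", None, self.delta_cost_government / 1e9),
            ("icer_healthcare_usd_per_qaly", None, self.icer_healthcare.value),
            ("icer_government_usd_per_qaly", None, self.icer_government.value),
            ("healthcare_saving_per_person_per_year_usd", None,
             self.saving_per_person_per_year),
        ]
        return pd.DataFrame(rows, columns=["item", "status_quo", "soda_tax"])


def evaluate_cea(trace_sq: Trace, trace_tax: Trace, drawn: DrawnParameters,
                 config: ModelConfig) -> CEAResult:
    """Accrue both arms under one parameter realisation and compare them."""
    rate, factor, horizon = config.discount_rate, config.rescale_factor, config.horizon_years
    cost_sq, qaly_sq = accrue(trace_sq, drawn.costs, drawn.utilities, rate)
    cost_tax, qaly_tax = accrue(trace_tax, drawn.costs, drawn.utilities, rate)
    cost_sq, cost_tax = rescale(cost_sq, factor), rescale(cost_tax, factor)
    qaly_sq, qaly_tax = rescale(qaly_sq, factor), rescale(qaly_tax, factor)

    af = annuity_factor(horizon, rate)
    revenue_total = drawn.annual_revenue * af
    admin_total = drawn.admin_cost_per_year * af

    d_cost_hc = cost_tax - cost_sq
    d_qaly = qaly_tax - qaly_sq
    d_cost_gov = d_cost_hc + admin_total - revenue_total

    population = config.n_individuals * factor
    saving_pp = ((cost_sq - cost_tax) / population / horizon) if horizon else 0.0

    return CEAResult(
        cost_sq=cost_sq, cost_tax=cost_tax, qaly_sq=qaly_sq, qaly_tax=qaly_tax,
        delta_cost_healthcare=d_cost_hc, delta_qaly=d_qaly,
        revenue_total=revenue_total, admin_cost_total=admin_total,
        delta_cost_government=d_cost_gov,
        icer_healthcare=icer(cost_tax, cost_sq, qaly_tax, qaly_sq),
        icer_government=icer(cost_tax + admin_total - revenue_total, cost_sq,
                             qaly_tax, qaly_sq),
        nmb_healthcare=config.wtp * d_qaly - d_cost_hc,
        nmb_government=config.wtp * d_qaly - d_cost_gov,
        saving_per_person_per_year=saving_pp,
        wtp=config.wtp, rescale_factor=factor,
    )
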