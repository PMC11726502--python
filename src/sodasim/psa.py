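"""Probabilistic sensitivity analysis.

Each iteration independently redraws every non-fixed input from its
moment-matched distribution (gamma for costs, beta for probabilities and
utilities, log-normal for ratio measures, normal for the sign-indefinite tax
weight effect), renormalises any transition row whose drawn probabilities
exceed the unit budget, re-simulates both arms with common random numbers,
and records the incremental cost (both perspectives) and incremental QALYs.
Summaries are means and 2.5/97.5 percentile intervals; the cost-effectiveness
acceptability curve (CEAC) is the fraction of iterations with positive net
monetary benefit as a function of the willingness-to-pay threshold.

Parameter uncertainty only is propagated: the baseline cohort is regenerated
from the same seed each iteration, and the natural-gain range — an interval,
not a distribution — stays fixed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics
from .engine import STATUS_QUO, simulate, soda_tax_arm
from .parameters import (Distribution, DrawnParameters, ModelConfig,
                         ParameterSet, UTILITY_GROUPS, fit_distribution,
                         renormalize_rows)
from .population import PopulationSpec, calibrate, generate_cohort
from .states import HealthState

#: Default WTP grid for the acceptability curve, $/QALY.
DEFAULT_WTP_GRID = tuple(range(0, 200_001, 10_000))

_MAX_SEED = 2**31 - 1


class _FittedSet:
    """Distributions fitted once per ParameterSet, reused across iterations."""

    def __init__(self, pset: ParameterSet):
        self.pset = pset
        self.transitions: dict[tuple, Distribution] = {
            key: fit_distribution(pv) for key, pv in pset.transitions.entries.items()}
        self.costs: dict[HealthState, Distribution] = {
            s: fit_distribution(pv) for s, pv in pset.costs.items()}
        self.utilities: dict[str, Distribution] = {
            g: fit_distribution(pv) for g, pv in pset.utilities.items()}
        self.weight_effect = fit_distribution(pset.weight_effect)
        self.revenue = fit_distribution(pset.annual_revenue)
        self.admin = fit_distribution(pset.admin_cost)


def draw_parameter_set(pset: ParameterSet, rng: np.random.Generator,
                       _fitted: _FittedSet | None = None) -> DrawnParameters:
    """One joint draw of all inputs; fixed parameters pass through unchanged.

    Drawn transition rows summing above 1 are renormalised proportionally so
    the residual stay probability stays non-negative.
    """
    fitted = _fitted or _FittedSet(pset)
    probs = {key: float(np.clip(dist.sample(rng), 0.0, 1.0))
             for key, dist in fitted.transitions.items()}
    probs = renormalize_rows(probs)
    costs = {s: float(dist.sample(rng)) for s, dist in fitted.costs.items()}
    costs[HealthState.DEATH] = 0.0
    utilities: dict[HealthState, float] = {}
    for group, dist in fitted.utilities.items():
        u = float(np.clip(dist.sample(rng), 0.0, 1.0))
        for s in UTILITY_GROUPS[group]:
            utilities[s] = u
    return DrawnParameters(
        transition_probs=probs, costs=costs, utilities=utilities,
        weight_effect=float(fitted.weight_effect.sample(rng)),
        annual_revenue=float(fitted.revenue.sample(rng)),
        admin_cost_per_year=float(fitted.admin.sample(rng)),
    )


@dataclass
class PSAResult:
    """Per-iteration incremental outcomes (population-rescaled) and summaries."""

    delta_cost_healthcare: np.ndarray
    delta_cost_government: np.ndarray
    delta_qaly: np.ndarray
    wtp: float = 100_000.0
    seed: int | None = None

    @property
    def n_iterations(self) -> int:
        return self.delta_qaly.size

    def _deltas(self, perspective: str) -> np.ndarray:
        if perspective == "healthcare":
            return self.delta_cost_healthcare
        if perspective == "government":
            return self.delta_cost_government
        raise ValueError(f"unknown perspective {perspective!r}")

    def icers(self, perspective: str = "healthcare") -> np.ndarray:
        d = self._deltas(perspective)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.delta_qaly != 0.0, d / self.delta_qaly, np.nan)

    def probability_cost_effective(self, wtp: float | None = None,
                                   perspective: str = "healthcare") -> float:
        """Fraction of iterations with positive net monetary benefit at ``wtp``."""
        wtp = self.wtp if wtp is None else wtp
        nmb = wtp * self.delta_qaly - self._deltas(perspective)
        return float((nmb > 0.0).mean())

    def summaries(self) -> pd.DataFrame:
        rows = []
        for name, arr in [("delta_cost_healthcare_usd", self.delta_cost_healthcare),
                          ("delta_cost_government_usd", self.delta_cost_government),
                          ("delta_qaly", self.delta_qaly),
                          ("icer_healthcare_usd_per_qaly", self.icers("healthcare"))]:
            clean = arr[np.isfinite(arr)]
            rows.append({
                "quantity": name,
                "mean": float(np.mean(clean)),
                "p2.5": float(np.percentile(clean, 2.5)),
                "p97.5": float(np.percentile(clean, 97.5)),
            })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "delta_cost_hc": self.delta_cost_healthcare,
            "delta_cost_gov": self.delta_cost_government,
            "delta_qaly": self.delta_qaly,
        })


def ceac(result: PSAResult, wtp_grid=DEFAULT_WTP_GRID,
         perspective: str = "healthcare") -> pd.DataFrame:
    """Acceptability curve: P(λ·Δqaly − Δcost > 0) on a WTP grid."""
    if result.n_iterations == 0:
        raise ValueError("CEAC requires at least one PSA iteration")
    probs = [result.probability_cost_effective(w, perspective) for w in wtp_grid]
    return pd.DataFrame({"wtp": list(wtp_grid), "probability": probs})


def run_psa(pset: ParameterSet, config: ModelConfig, n_iterations: int = 200,
            n_individuals: int = 2_000, seed: int = 0,
            pop_spec: PopulationSpec | None = None,
            progress: bool = False) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through both arms.

    The desk-scale default (200 iterations × 2,000 individuals) keeps the
    analysis interactive; the full profile is 1,000 × 20,000.  Everything is
    reproducible from ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    base = np.random.default_rng(seed)
    cal_seed = int(base.integers(_MAX_SEED))
    cohort_seed = int(base.integers(_MAX_SEED))
    sim_seeds = base.integers(_MAX_SEED, size=n_iterations)
    if pop_spec is None:
        pop_spec = calibrate(seed=cal_seed)
    cohort = generate_cohort(pop_spec.with_n(n_individuals), cohort_seed)
    # keep population-scale totals invariant to the per-iteration cohort size
    factor = config.rescale_factor * config.n_individuals / n_individuals
    cfg = config.replace(n_individuals=n_individuals, rescale_factor=factor)
    fitted = _FittedSet(pset)

    d_hc = np.empty(n_iterations)
    d_gov = np.empty(n_iterations)
    d_q = np.empty(n_iterations)
    iterator = range(n_iterations)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="PSA")
        except ImportError:
            pass
    for i in iterator:
        drawn = draw_parameter_set(pset, base, _fitted=fitted)
        s = int(sim_seeds[i])
        trace_sq, _ = simulate(cohort, STATUS_QUO, drawn.transition_probs, cfg, seed=s)
        trace_tax, _ = simulate(cohort, soda_tax_arm(drawn.weight_effect),
                                drawn.transition_probs, cfg, seed=s)
        res = economics.evaluate_cea(trace_sq, trace_tax, drawn, cfg)
        d_hc[i] = res.delta_cost_healthcare
        d_gov[i] = res.delta_cost_government
        d_q[i] = res.delta_qaly
    return PSAResult(d_hc, d_gov, d_q, wtp=config.wtp, seed=seed)
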