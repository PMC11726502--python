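"""Annual-cycle microsimulation of the two policy arms.

Each of the 20 one-year cycles applies, in order and for every alive
individual: (1) the weight step — an independent uniform draw from the
natural-gain range plus the arm's tax weight effect; (2) BMI
reclassification for individuals in a weight-governed state; (3) at most one
sampled transition from the current state's annual-probability row, with the
residual mass meaning "remain"; (4) tunnel promotion — an individual who
entered acute stroke (MI) in the previous cycle and did not transition moves
to the chronic poststroke (post-MI) state.  Death is absorbing.

Both arms are simulated with common random numbers: per-cycle draws are made
for every individual (dead or alive, so streams never desynchronise), and
identical seeds give identical draws, so the arms differ only through the
tax weight effect.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelConfig
from .population import Cohort, classify_bmi
from .states import (HealthState, N_STATES, STATE_NAMES, TUNNEL_SUCCESSOR,
                     WEIGHT_GOVERNED)

#: Weights are floored here to keep extreme PSA draws physical.
WEIGHT_FLOOR_KG = 30.0

#: Incident-event labels paired with the state whose first-ever entry they count.
EVENT_STATES = (
    ("new_overweight", HealthState.OVERWEIGHT),
    ("new_obesity", HealthState.OBESITY),
    ("new_diabetes", HealthState.DIABETES),
    ("new_stroke", HealthState.STROKE),
    ("new_mi", HealthState.MI),
    ("new_esrd", HealthState.ESRD),
)

EVENT_TYPES = tuple(name for name, _ in EVENT_STATES) + (
    "deaths", "person_cycles_overweight", "person_cycles_obese")


@dataclass(frozen=True)
class ArmSpec:
    """A policy arm: its name and the annual tax-mediated weight change (kg/y)."""

    name: str
    weight_effect: float = 0.0

    def __post_init__(self):
        if self.name == "status_quo" and self.weight_effect != 0.0:
            raise ValueError("the status-quo arm has no tax weight effect")


STATUS_QUO = ArmSpec("status_quo", 0.0)


def soda_tax_arm(weight_effect: float = -0.56) -> ArmSpec:
    return ArmSpec("soda_tax", weight_effect)


# ---------------------------------------------------------------------------
# Weight-effect provenance chain
# ---------------------------------------------------------------------------

def weight_step(weight, weight_effect: float, gain, floor: float = WEIGHT_FLOOR_KG):
    """One annual weight update: weight + natural gain + tax effect, floored."""
    return np.maximum(np.asarray(weight, dtype=float) + np.asarray(gain) + weight_effect,
                      floor)


def sugar_to_calories(grams_per_day: float, kcal_per_gram: float = 4.0) -> float:
    """Added-sugar intake (g/day) to energy intake (kcal/day)."""
    return kcal_per_gram * grams_per_day


def calories_to_weight_rate(kcal_per_day: float, days_per_year: float = 365,
                            kcal_per_pound: float = 3500.0,
                            lb_per_kg: float = 2.20462) -> float:
    """Steady energy surplus (kcal/day) to annual weight change (kg/y).

    Static 3,500-kcal-per-pound model.  With the default constants a 12.32
    kcal/day deficit maps to about 0.58 kg/y; the headline tax effect is
    nevertheless taken from the input table (−0.56 kg/y), so this converter
    documents the provenance chain rather than feeding the simulation.
    """
    return kcal_per_day * days_per_year / kcal_per_pound / lb_per_kg


# ---------------------------------------------------------------------------
# Compiled transitions
# ---------------------------------------------------------------------------

class CompiledTransitions:
    """Per-origin destination/cumulative-probability arrays for fast sampling."""

    def __init__(self, probs: dict[tuple[HealthState, HealthState], float]):
        rows: dict[HealthState, list[tuple[HealthState, float]]] = {}
        for (o, d), p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {STATE_NAMES[o]}->{STATE_NAMES[d]} = {p}")
            rows.setdefault(o, []).append((d, p))
        self.rows: list[tuple[int, np.ndarray, np.ndarray]] = []
        for o, pairs in rows.items():
            dests = np.array([int(d) for d, _ in pairs], dtype=np.int8)
            cum = np.cumsum([p for _, p in pairs])
            if cum[-1] > 1.0 + 1e-9:
                raise ValueError(
                    f"outgoing probabilities from {STATE_NAMES[o]} sum to {cum[-1]:.4f} > 1")
            self.rows.append((int(o), dests, cum))


# ---------------------------------------------------------------------------
# Trace
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Per-cycle state occupancy and incident-event counts for one arm."""

    state_counts: np.ndarray          # (horizon, N_STATES) ints
    events: pd.DataFrame              # (horizon, len(EVENT_TYPES)) ints
    n: int
    arm: str = ""

    @property
    def horizon(self) -> int:
        return self.state_counts.shape[0]

    def alive_counts(self) -> np.ndarray:
        return self.n - self.state_counts[:, HealthState.DEATH]

    def total_events(self, event: str) -> int:
        return int(self.events[event].sum())

    def to_long_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        states = pd.DataFrame(
            [(t, STATE_NAMES[HealthState(s)], int(self.state_counts[t, s]))
             for t in range(self.horizon) for s in range(N_STATES)],
            columns=["cycle", "state", "count"])
        events = self.events.reset_index(names="cycle").melt(
            id_vars="cycle", var_name="event", value_name="count")
        return states, events


# ---------------------------------------------------------------------------
# Cycle and horizon advancement
# ---------------------------------------------------------------------------

_WEIGHT_CODES = np.array([int(s) for s in WEIGHT_GOVERNED], dtype=np.int8)


def advance_cycle(cohort: Cohort, arm: ArmSpec, transitions: CompiledTransitions,
                  rng: np.random.Generator,
                  gain_range: tuple[float, float] = (0.45, 0.91),
                  weight_floor: float = WEIGHT_FLOOR_KG) -> dict[str, int]:
    """Advance the cohort by one cycle in place; return the cycle's event counts.

    Draws one natural-gain uniform and one transition uniform per individual
    (including the dead, to keep streams aligned across arms).
    """
    n = cohort.n
    alive0 = cohort.alive.copy()
    start_state = cohort.state.copy()
    gains = rng.uniform(gain_range[0], gain_range[1], n)
    u = rng.random(n)

    # (1) weight dynamics
    cohort.weight[alive0] = weight_step(cohort.weight[alive0], arm.weight_effect,
                                        gains[alive0], weight_floor)

    # (2) BMI reclassification for weight-governed states
    wg = alive0 & np.isin(cohort.state, _WEIGHT_CODES)
    if wg.any():
        cohort.state[wg] = classify_bmi(cohort.weight[wg], cohort.height[wg])

    # (3) at most one sampled transition from the current state's row
    pre = cohort.state.copy()
    for origin, dests, cum in transitions.rows:
        m = alive0 & (pre == origin)
        if not m.any():
            continue
        idx = np.searchsorted(cum, u[m], side="right")
        hit = idx < dests.size
        new = np.where(hit, dests[np.minimum(idx, dests.size - 1)], origin)
        cohort.state[m] = new.astype(np.int8)

    # (4) tunnel promotion for acute-event survivors of a full cycle
    for acute, post in TUNNEL_SUCCESSOR.items():
        promote = alive0 & (start_state == acute) & (cohort.state == acute)
        cohort.state[promote] = np.int8(post)

    newly_dead = alive0 & (cohort.state == HealthState.DEATH)
    cohort.alive[newly_dead] = False

    changed = cohort.state != start_state
    cohort.tenure[changed] = 0
    cohort.tenure[alive0 & ~changed] += 1

    events: dict[str, int] = {}
    for name, s in EVENT_STATES:
        entered = alive0 & (cohort.state == s) & ~cohort.ever[s]
        cohort.ever[s][entered] = True
        events[name] = int(entered.sum())
    events["deaths"] = int(newly_dead.sum())
    events["person_cycles_overweight"] = int((cohort.state == HealthState.OVERWEIGHT).sum())
    events["person_cycles_obese"] = int((cohort.state == HealthState.OBESITY).sum())
    return events


def simulate(cohort: Cohort, arm: ArmSpec,
             transition_probs: dict[tuple[HealthState, HealthState], float],
             config: ModelConfig, seed: int | None = None,
             costs: dict[HealthState, float] | None = None,
             utilities: dict[HealthState, float] | None = None) -> tuple[Trace, Cohort]:
    """Run the cohort through the full horizon under one arm.

    Returns the per-cycle Trace and the terminal cohort (a copy; the input
    is untouched).  If cost/utility schedules are given, per-individual
    discounted totals are accrued as well: the state occupied after the
    cycle's updates earns that cycle's (discounted) cost and utility, so a
    cycle ending in death accrues nothing.
    """
    cohort = cohort.copy()
    compiled = (transition_probs if isinstance(transition_probs, CompiledTransitions)
                else CompiledTransitions(transition_probs))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    horizon = config.horizon_years
    counts = np.zeros((horizon, N_STATES), dtype=np.int64)
    ev = {name: np.zeros(horizon, dtype=np.int64) for name in EVENT_TYPES}
    cost_arr = util_arr = None
    if costs is not None:
        cost_arr = np.array([costs[HealthState(s)] for s in range(N_STATES)])
    if utilities is not None:
        util_arr = np.array([utilities[HealthState(s)] for s in range(N_STATES)])
    for t in range(horizon):
        cycle_events = advance_cycle(cohort, arm, compiled, rng,
                                     gain_range=config.natural_gain_range)
        counts[t] = np.bincount(cohort.state, minlength=N_STATES)
        for name, v in cycle_events.items():
            ev[name][t] = v
        df = (1.0 + config.discount_rate) ** (-t)
        if cost_arr is not None:
            cohort.disc_cost += cost_arr[cohort.state] * df
        if util_arr is not None:
            cohort.disc_qaly += util_arr[cohort.state] * df
    trace = Trace(counts, pd.DataFrame(ev), n=cohort.n, arm=arm.name)
    return trace, cohort
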