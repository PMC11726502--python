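"""Model inputs: point values, uncertainty intervals, and PSA distributions.

This module ingests the structured parameter table that drives the model
(annual per-state costs in 2022 USD, EQ-5D utilities, annual transition
probabilities, the tax weight effect, and tax revenue/administration flows),
validates it, derives missing ±25% bounds, converts heterogeneous source
measures (multi-year risks, risk/hazard/odds/incidence-rate ratios) to
one-year transition probabilities, and moment-matches the distribution
families used by the probabilistic sensitivity analysis.

Conventions
-----------
* A 95% interval (and, by the same rule, a ±25% interval) maps to a standard
  deviation of (high − low) / 3.92.
* Costs draw from gamma, utilities and probabilities from beta, ratio
  measures from log-normal, and the sign-indefinite tax weight effect from a
  normal distribution.  Every fitted distribution reproduces the point value
  as its analytic mean.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .states import HealthState, N_STATES, STATE_NAMES, state_from_name

#: Width of a 95% normal interval in standard-deviation units.
CI95_SPAN = 3.92

UNCERTAINTY_KINDS = ("ci95", "pm25", "fixed")
FAMILIES = ("gamma", "beta", "lognormal", "normal", "fixed")


class ParameterError(ValueError):
    """Base class for parameter ingestion problems."""


class MissingParameterError(ParameterError):
    """A required named parameter is absent from the configuration."""


class ValidationError(ParameterError):
    """A parameter value violates its domain invariant."""


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------

def pm25_bounds(mean: float) -> tuple[float, float]:
    """Return the (low, high) = (0.75·mean, 1.25·mean) interval.

    The interval convention used for inputs whose sources report no
    confidence interval: plus and minus 25% of the value.
    """
    if not math.isfinite(mean):
        raise ValidationError(f"pm25_bounds requires a finite mean, got {mean}")
    lo, hi = 0.75 * mean, 1.25 * mean
    return (min(lo, hi), max(lo, hi))


def multi_year_risk_to_annual(risk: float, years: int) -> float:
    """Convert a k-year cumulative risk to a 1-year transition probability.

    Assumes a constant hazard over the k years: p1 = 1 − (1 − pk)^(1/k).
    """
    if years < 1:
        raise ValidationError(f"years must be >= 1, got {years}")
    if not 0.0 <= risk < 1.0:
        if risk == 1.0 and years > 1:
            raise ValidationError("a certain k-year risk has no unique annual probability")
        raise ValidationError(f"risk must lie in [0, 1), got {risk}")
    return 1.0 - (1.0 - risk) ** (1.0 / years)


def ratio_to_probability(p_ref: float, ratio: float, kind: str) -> float:
    """Apply a ratio measure to a reference probability.

    kind:
        ``rr``        risk ratio: p = min(1, ratio · p_ref)
        ``hr``/``irr`` hazard or incidence-rate ratio: p = 1 − (1 − p_ref)^ratio
        ``or``        odds ratio: p = ratio·p_ref / (1 − p_ref + ratio·p_ref)
    """
    if not 0.0 <= p_ref < 1.0:
        raise ValidationError(f"p_ref must lie in [0, 1), got {p_ref}")
    if ratio <= 0.0:
        raise ValidationError(f"ratio must be positive, got {ratio}")
    kind = kind.lower()
    if kind == "rr":
        return min(1.0, ratio * p_ref)
    if kind in ("hr", "irr"):
        return 1.0 - (1.0 - p_ref) ** ratio
    if kind == "or":
        return ratio * p_ref / (1.0 - p_ref + ratio * p_ref)
    raise ValidationError(f"unknown ratio kind {kind!r}; expected rr, hr, irr or or")


# ---------------------------------------------------------------------------
# ParameterValue and distribution fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterValue:
    """A named model input with its point value and uncertainty encoding."""

    name: str
    mean: float
    low: float | None = None
    high: float | None = None
    uncertainty_kind: str = "fixed"
    family: str = "fixed"

    def __post_init__(self):
        if self.uncertainty_kind not in UNCERTAINTY_KINDS:
            raise ValidationError(
                f"{self.name}: unknown uncertainty kind {self.uncertainty_kind!r}")
        if self.family not in FAMILIES:
            raise ValidationError(f"{self.name}: unknown family {self.family!r}")
        if self.uncertainty_kind != "fixed":
            if self.low is None or self.high is None:
                raise ValidationError(f"{self.name}: {self.uncertainty_kind} requires bounds")
            if not (self.low <= self.mean <= self.high):
                raise ValidationError(
                    f"{self.name}: bounds must bracket the mean "
                    f"(low={self.low}, mean={self.mean}, high={self.high})")

    @property
    def sd(self) -> float:
        """Standard deviation implied by the interval, (high − low) / 3.92."""
        if self.uncertainty_kind == "fixed" or self.low is None or self.high is None:
            return 0.0
        return (self.high - self.low) / CI95_SPAN

    @property
    def is_fixed(self) -> bool:
        return self.uncertainty_kind == "fixed" or self.sd == 0.0

    def replace(self, **kw) -> "ParameterValue":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Distribution:
    """A fitted sampling distribution whose analytic mean equals the input mean."""

    family: str
    mean: float
    params: tuple[float, ...] = ()

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size)
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, size)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size)
        if self.family == "normal":
            m, s = self.params
            return rng.normal(m, s, size)
        raise ValidationError(f"unknown family {self.family!r}")


def fit_distribution(pv: ParameterValue) -> Distribution:
    """Moment-match a sampling distribution to (mean, sd) for the PSA.

    gamma: shape = mean²/sd², scale = sd²/mean.
    beta: α = mean·ν, β = (1 − mean)·ν with ν = mean(1 − mean)/sd² − 1;
          sd is clipped below the beta-feasible bound when necessary.
    lognormal: σ² = ln(1 + (sd/mean)²), μ = ln mean − σ²/2.
    normal: (mean, sd).

    Degenerate inputs (sd = 0, family "fixed", or a mean outside the family's
    support) collapse to a point mass at the mean; the non-positive-mean case
    for gamma/lognormal emits a warning.
    """
    m, sd = pv.mean, pv.sd
    if pv.family == "fixed" or sd == 0.0:
        return Distribution("fixed", m)
    if pv.family == "gamma":
        if m <= 0.0:
            warnings.warn(f"{pv.name}: gamma requires mean > 0; treating as fixed")
            return Distribution("fixed", m)
        return Distribution("gamma", m, (m * m / (sd * sd), sd * sd / m))
    if pv.family == "beta":
        if not 0.0 < m < 1.0:
            # utility of exactly 1 (or 0): no spread is beta-feasible
            return Distribution("fixed", m)
        sd_max = math.sqrt(m * (1.0 - m))
        if sd >= sd_max:
            sd = 0.99 * sd_max
        nu = m * (1.0 - m) / (sd * sd) - 1.0
        if nu <= 0.0:
            return Distribution("fixed", m)
        return Distribution("beta", m, (m * nu, (1.0 - m) * nu))
    if pv.family == "lognormal":
        if m <= 0.0:
            warnings.warn(f"{pv.name}: lognormal requires mean > 0; treating as fixed")
            return Distribution("fixed", m)
        sigma2 = math.log1p((sd / m) ** 2)
        return Distribution("lognormal", m, (math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)))
    if pv.family == "normal":
        return Distribution("normal", m, (m, sd))
    raise ValidationError(f"{pv.name}: unknown family {pv.family!r}")


# ---------------------------------------------------------------------------
# Transition table
# ---------------------------------------------------------------------------

#: Origin states with at least one parameterised outgoing transition.
TRANSITION_ORIGINS = (
    HealthState.NORMAL, HealthState.OVERWEIGHT, HealthState.OBESITY,
    HealthState.DIABETES, HealthState.STROKE, HealthState.MI,
    HealthState.ESRD, HealthState.POSTSTROKE, HealthState.POSTMI,
)

#: The 30 (origin, destination) pairs the default model parameterises.
REQUIRED_TRANSITIONS: tuple[tuple[HealthState, HealthState], ...] = tuple(
    (state_from_name(o), state_from_name(d))
    for o, d in [
        ("normal", "diabetes"), ("normal", "stroke"), ("normal", "mi"),
        ("normal", "esrd"), ("normal", "death"),
        ("overweight", "diabetes"), ("overweight", "stroke"), ("overweight", "mi"),
        ("overweight", "esrd"), ("overweight", "death"),
        ("obesity", "diabetes"), ("obesity", "stroke"), ("obesity", "mi"),
        ("obesity", "esrd"), ("obesity", "death"),
        ("diabetes", "stroke"), ("diabetes", "mi"), ("diabetes", "esrd"),
        ("diabetes", "death"),
        ("stroke", "mi"), ("stroke", "death"),
        ("mi", "stroke"), ("mi", "death"),
        ("esrd", "stroke"), ("esrd", "mi"), ("esrd", "death"),
        ("poststroke", "mi"), ("poststroke", "death"),
        ("postmi", "stroke"), ("postmi", "death"),
    ]
)


def renormalize_rows(
    probs: Mapping[tuple[HealthState, HealthState], float],
) -> dict[tuple[HealthState, HealthState], float]:
    """Scale any origin row whose outgoing probabilities sum above 1.

    Probability is conserved by shrinking the whole row proportionally so the
    residual stay probability is never negative (relevant after PSA draws).
    """
    out = dict(probs)
    rows: dict[HealthState, float] = {}
    for (o, _d), p in probs.items():
        rows[o] = rows.get(o, 0.0) + p
    for o, total in rows.items():
        if total > 1.0:
            for key in list(out):
                if key[0] == o:
                    out[key] = out[key] / total
    return out


@dataclass
class TransitionTable:
    """Annual transition probabilities keyed by (origin, destination).

    The residual 1 − Σp of each origin row is the stay/continuation
    probability; death is absorbing and has no outgoing entries.
    """

    entries: dict[tuple[HealthState, HealthState], ParameterValue]

    def validate(self) -> None:
        for (o, d), pv in self.entries.items():
            if o == HealthState.DEATH:
                raise ValidationError("death is absorbing; it cannot have outgoing entries")
            if not 0.0 <= pv.mean <= 1.0:
                raise ValidationError(
                    f"transition {STATE_NAMES[o]}->{STATE_NAMES[d]}: "
                    f"probability {pv.mean} outside [0, 1]")
        for o in {o for o, _ in self.entries}:
            s = self.row_sum(o)
            if s > 1.0 + 1e-12:
                raise ValidationError(
                    f"outgoing probabilities from {STATE_NAMES[o]} sum to {s:.4f} > 1")

    def row(self, origin: HealthState) -> dict[HealthState, ParameterValue]:
        return {d: pv for (o, d), pv in self.entries.items() if o == origin}

    def row_sum(self, origin: HealthState) -> float:
        return sum(pv.mean for (o, _d), pv in self.entries.items() if o == origin)

    def central(self) -> dict[tuple[HealthState, HealthState], float]:
        """Point-value probabilities, ready for the simulation engine."""
        return {key: pv.mean for key, pv in self.entries.items()}

    @staticmethod
    def matrix(probs: Mapping[tuple[HealthState, HealthState], float]) -> np.ndarray:
        """Dense row-stochastic matrix with the residual on the diagonal."""
        mat = np.zeros((N_STATES, N_STATES))
        for (o, d), p in probs.items():
            mat[o, d] = p
        for s in HealthState:
            mat[s, s] = 1.0 - mat[s].sum() + mat[s, s]
        mat[HealthState.DEATH] = 0.0
        mat[HealthState.DEATH, HealthState.DEATH] = 1.0
        return mat

    # -- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "origin": STATE_NAMES[o],
                "destination": STATE_NAMES[d],
                "probability": pv.mean,
                "low": pv.low,
                "high": pv.high,
                "uncertainty_kind": pv.uncertainty_kind,
            }
            for (o, d), pv in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransitionTable":
        df = pd.read_csv(path)
        entries = {}
        for rec in df.to_dict("records"):
            o, d = state_from_name(rec["origin"]), state_from_name(rec["destination"])
            kind = rec["uncertainty_kind"]
            low = None if pd.isna(rec.get("low")) else float(rec["low"])
            high = None if pd.isna(rec.get("high")) else float(rec["high"])
            entries[(o, d)] = ParameterValue(
                name=f"{rec['origin']}->{rec['destination']}",
                mean=float(rec["probability"]), low=low, high=high,
                uncertainty_kind=kind,
                family="fixed" if kind == "fixed" else "beta",
            )
        table = cls(entries)
        table.validate()
        return table


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Run settings and physical constants of the weight-effect chain."""

    n_individuals: int = 20_000
    horizon_years: int = 20
    cycle_length: float = 1.0
    discount_rate: float = 0.03
    rescale_factor: float = 1_462.36
    wtp: float = 100_000.0
    calories_per_gram_sugar: float = 4.0
    kcal_per_pound: float = 3_500.0
    lb_per_kg: float = 2.20462
    days_per_year: int = 365
    natural_gain_range: tuple[float, float] = (0.45, 0.91)
    tax_weight_effect: float = -0.56
    annual_revenue: float = 862_722_888.0
    admin_cost_fraction: float = 0.01
    seed: int = 20150101

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")
        if self.horizon_years < 0:
            raise ValidationError("horizon_years must be >= 0")
        if self.rescale_factor <= 0:
            raise ValidationError("rescale_factor must be > 0")
        lo, hi = self.natural_gain_range
        if lo > hi:
            raise ValidationError("natural_gain_range low must be <= high")
        if not 0.0 <= self.admin_cost_fraction <= 1.0:
            raise ValidationError("admin_cost_fraction must lie in [0, 1]")

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        kw = dict(d)
        if "natural_gain_range" in kw:
            kw["natural_gain_range"] = tuple(float(x) for x in kw["natural_gain_range"])
        return cls(**kw)


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------

#: Utility groups as parameterised: acute and chronic stroke (and MI) share
#: one utility input and therefore one PSA draw.
UTILITY_GROUPS: dict[str, tuple[HealthState, ...]] = {
    "normal": (HealthState.NORMAL,),
    "overweight": (HealthState.OVERWEIGHT,),
    "obesity": (HealthState.OBESITY,),
    "diabetes": (HealthState.DIABETES,),
    "stroke_poststroke": (HealthState.STROKE, HealthState.POSTSTROKE),
    "mi_postmi": (HealthState.MI, HealthState.POSTMI),
    "esrd": (HealthState.ESRD,),
    "death": (HealthState.DEATH,),
}

#: States carrying an explicit annual cost entry (death is implicitly 0).
COST_STATES = tuple(s for s in HealthState if s != HealthState.DEATH)


@dataclass(frozen=True)
class DrawnParameters:
    """One concrete realisation of every model input (point values or a PSA draw)."""

    transition_probs: dict[tuple[HealthState, HealthState], float]
    costs: dict[HealthState, float]
    utilities: dict[HealthState, float]
    weight_effect: float
    annual_revenue: float
    admin_cost_per_year: float


@dataclass
class ParameterSet:
    """All model inputs with point values, bounds, and PSA families."""

    transitions: TransitionTable
    costs: dict[HealthState, ParameterValue]
    utilities: dict[str, ParameterValue]
    weight_effect: ParameterValue
    annual_revenue: ParameterValue
    admin_cost: ParameterValue

    def validate(self) -> None:
        self.transitions.validate()
        for s in COST_STATES:
            if s not in self.costs:
                raise MissingParameterError(f"missing cost entry for state {STATE_NAMES[s]}")
            if self.costs[s].mean < 0:
                raise ValidationError(f"cost for {STATE_NAMES[s]} must be >= 0")
        for g in UTILITY_GROUPS:
            if g not in self.utilities:
                raise MissingParameterError(f"missing utility entry {g!r}")
            u = self.utilities[g]
            if not 0.0 <= u.mean <= 1.0:
                raise ValidationError(f"utility {g!r} = {u.mean} outside [0, 1]")

    def cost_schedule(self) -> dict[HealthState, float]:
        sched = {s: self.costs[s].mean for s in COST_STATES}
        sched[HealthState.DEATH] = 0.0
        return sched

    def utility_schedule(self) -> dict[HealthState, float]:
        sched: dict[HealthState, float] = {}
        for group, states in UTILITY_GROUPS.items():
            for s in states:
                sched[s] = self.utilities[group].mean
        return sched

    def central(self) -> DrawnParameters:
        """Point-value realisation used for the deterministic base case."""
        return DrawnParameters(
            transition_probs=self.transitions.central(),
            costs=self.cost_schedule(),
            utilities=self.utility_schedule(),
            weight_effect=self.weight_effect.mean,
            annual_revenue=self.annual_revenue.mean,
            admin_cost_per_year=self.admin_cost.mean,
        )


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------

_REQUIRED_SCALARS = ("weight_change_soda_tax", "tax_revenue_per_year", "admin_cost_per_year")


def _parse_value(name: str, raw: Mapping, default_family: str,
                 lower: float | None = None, upper: float | None = None) -> ParameterValue:
    if not isinstance(raw, Mapping) or "mean" not in raw:
        raise ValidationError(f"{name}: entry must be a mapping with a 'mean' field")
    mean = float(raw["mean"])
    kind = raw.get("uncertainty", raw.get("uncertainty_kind"))
    low = raw.get("low")
    high = raw.get("high")
    if kind is None:
        kind = "ci95" if low is not None and high is not None else "fixed"
    if kind == "pm25" and (low is None or high is None):
        low, high = pm25_bounds(mean)
    family = raw.get("family", default_family if kind != "fixed" else "fixed")
    pv = ParameterValue(name=name, mean=mean,
                        low=None if low is None else float(low),
                        high=None if high is None else float(high),
                        uncertainty_kind=kind, family=family)
    for bound, label in ((lower, "lower"), (upper, "upper")):
        if bound is not None:
            if (label == "lower" and mean < bound) or (label == "upper" and mean > bound):
                raise ValidationError(f"{name}: mean {mean} outside the admissible range")
    return pv


def _default_config_path() -> Path:
    return Path(__file__).resolve().parent / "data" / "default_parameters.yaml"


def load_parameters(source=None) -> tuple[ParameterSet, ModelConfig]:
    """Load the model inputs and run settings from YAML (or a parsed mapping).

    ``source`` may be None (packaged defaults), a path, a YAML string, or a
    mapping.  Missing ±25% bounds are derived; every value is validated.
    """
    if source is None:
        raw = yaml.safe_load(_default_config_path().read_text())
    elif isinstance(source, Mapping):
        raw = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValidationError("configuration must parse to a mapping")

    config = ModelConfig.from_dict(raw.get("run", {}))

    # -- transitions -------------------------------------------------------
    trans_raw = raw.get("transitions", {})
    entries: dict[tuple[HealthState, HealthState], ParameterValue] = {}
    for o_name, row in trans_raw.items():
        o = state_from_name(o_name)
        for d_name, cell in row.items():
            d = state_from_name(d_name)
            name = f"{STATE_NAMES[o]}->{STATE_NAMES[d]}"
            pv = _parse_value(name, cell, default_family="beta", lower=0.0, upper=1.0)
            if not 0.0 <= pv.mean <= 1.0:
                raise ValidationError(f"{name}: probability {pv.mean} outside [0, 1]")
            entries[(o, d)] = pv
    for o, d in REQUIRED_TRANSITIONS:
        if (o, d) not in entries:
            raise MissingParameterError(
                f"missing transition entry {STATE_NAMES[o]}->{STATE_NAMES[d]}")

    # -- costs -------------------------------------------------------------
    costs_raw = raw.get("costs", {})
    costs: dict[HealthState, ParameterValue] = {}
    for s_name, cell in costs_raw.items():
        s = state_from_name(s_name)
        costs[s] = _parse_value(f"cost:{STATE_NAMES[s]}", cell,
                                default_family="gamma", lower=0.0)
    for s in COST_STATES:
        if s not in costs:
            raise MissingParameterError(f"missing cost entry for state {STATE_NAMES[s]}")

    # -- utilities ---------------------------------------------------------
    utils_raw = raw.get("utilities", {})
    utilities: dict[str, ParameterValue] = {}
    for g_name, cell in utils_raw.items():
        if g_name not in UTILITY_GROUPS:
            raise ValidationError(f"unknown utility group {g_name!r}")
        pv = _parse_value(f"utility:{g_name}", cell, default_family="beta",
                          lower=0.0, upper=1.0)
        if not 0.0 <= pv.mean <= 1.0:
            raise ValidationError(f"utility:{g_name}: value {pv.mean} outside [0, 1]")
        utilities[g_name] = pv
    for g_name in UTILITY_GROUPS:
        if g_name not in utilities:
            raise MissingParameterError(f"missing utility entry {g_name!r}")

    # -- scalar parameters -------------------------------------------------
    scalars_raw = raw.get("parameters", {})
    for name in _REQUIRED_SCALARS:
        if name not in scalars_raw:
            raise MissingParameterError(f"missing parameter {name!r}")
    weight_effect = _parse_value("weight_change_soda_tax",
                                 scalars_raw["weight_change_soda_tax"],
                                 default_family="normal")
    revenue = _parse_value("tax_revenue_per_year", scalars_raw["tax_revenue_per_year"],
                           default_family="gamma", lower=0.0)
    admin = _parse_value("admin_cost_per_year", scalars_raw["admin_cost_per_year"],
                         default_family="gamma", lower=0.0)

    pset = ParameterSet(
        transitions=TransitionTable(entries),
        costs=costs,
        utilities=utilities,
        weight_effect=weight_effect,
        annual_revenue=revenue,
        admin_cost=admin,
    )
    pset.validate()
    return pset, config
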