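"""Synthetic baseline cohort of California adults.

The study population is adults (18+) in California in 2015.  Because the
underlying survey microdata cannot ship with the package, the baseline
cohort is drawn from a parametric joint weight/height distribution — a
log-normal weight marginal (right-skewed, strictly positive) and a normal
height marginal coupled by a Gaussian copula — calibrated so the simulated
cohort reproduces the survey's printed moments: mean weight 77.67 kg,
standard deviation 19.96 kg, and 28.2% obesity prevalence.

The weight marginal is matched to the mean/SD targets in closed form via the
log-normal moment formulas; the weight–height correlation is then adjusted
by a one-dimensional root search until the implied obesity prevalence
(BMI >= 30 with BMI = weight/height²) hits its target.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .states import HealthState, state_from_name

OVERWEIGHT_BMI = 25.0
OBESITY_BMI = 30.0
HEIGHT_MIN, HEIGHT_MAX = 1.2, 2.2


class CalibrationError(RuntimeError):
    """The correlation search could not bracket the prevalence target."""


@dataclass(frozen=True)
class CalibrationTargets:
    """Survey moments the synthetic cohort is calibrated to reproduce."""

    mean_weight: float = 77.67   # kg
    sd_weight: float = 19.96     # kg
    obesity_prev: float = 0.282  # fraction with BMI >= 30


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of the joint weight/height distribution."""

    n: int
    mean_log_weight: float
    sd_log_weight: float
    mean_height: float = 1.68    # m; free nuisance dimension, not printed
    sd_height: float = 0.10      # m
    corr: float = 0.4
    targets: CalibrationTargets = field(default_factory=CalibrationTargets)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_log_weight <= 0 or self.sd_height <= 0:
            raise ValueError("spread parameters must be > 0")
        if not -1.0 < self.corr < 1.0:
            raise ValueError("corr must lie strictly inside (-1, 1)")

    def with_n(self, n: int) -> "PopulationSpec":
        return dataclasses.replace(self, n=n)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def classify_bmi(weight, height):
    """BMI category from weight (kg) and height (m).

    Returns NORMAL for BMI < 25, OVERWEIGHT for 25 <= BMI < 30 and OBESITY
    for BMI >= 30 (both thresholds inclusive on the heavier side).  Accepts
    scalars or arrays; arrays return an integer state-code array.
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise ValueError("height must be positive")
    bmi = w / (h * h)
    codes = np.where(bmi >= OBESITY_BMI, int(HealthState.OBESITY),
                     np.where(bmi >= OVERWEIGHT_BMI, int(HealthState.OVERWEIGHT),
                              int(HealthState.NORMAL)))
    if np.isscalar(weight) and np.isscalar(height):
        return HealthState(int(codes))
    return codes


class Cohort:
    """Vectorised container for the simulated individuals.

    Columns: weight (kg), height (m), state (HealthState codes), tenure
    (years in current state), alive flag, and accumulated discounted cost
    (USD) and QALYs.  ``ever`` tracks which states each individual has ever
    occupied, which the reporting layer uses to count category/disease cases.
    """

    TRACKED_EVER = (HealthState.OVERWEIGHT, HealthState.OBESITY, HealthState.DIABETES,
                    HealthState.STROKE, HealthState.MI, HealthState.ESRD)

    def __init__(self, weight, height, state, tenure=None, alive=None,
                 disc_cost=None, disc_qaly=None, ever=None):
        self.weight = np.asarray(weight, dtype=float)
        self.height = np.asarray(height, dtype=float)
        self.state = np.asarray(state, dtype=np.int8)
        n = self.weight.size
        self.tenure = np.zeros(n, dtype=np.int32) if tenure is None else np.asarray(tenure)
        self.alive = (np.ones(n, dtype=bool) if alive is None
                      else np.asarray(alive, dtype=bool))
        self.disc_cost = (np.zeros(n) if disc_cost is None
                          else np.asarray(disc_cost, dtype=float))
        self.disc_qaly = (np.zeros(n) if disc_qaly is None
                          else np.asarray(disc_qaly, dtype=float))
        if ever is None:
            ever = {s: self.state == s for s in self.TRACKED_EVER}
        self.ever = ever
        self._check()

    def _check(self):
        if np.any(self.weight <= 0):
            raise ValueError("weights must be positive")
        if np.any((self.height < HEIGHT_MIN) | (self.height > HEIGHT_MAX)):
            raise ValueError(f"heights must lie in [{HEIGHT_MIN}, {HEIGHT_MAX}] m")
        dead = self.state == HealthState.DEATH
        if np.any(dead & self.alive):
            raise ValueError("individuals in the death state cannot be alive")

    @property
    def n(self) -> int:
        return self.weight.size

    def copy(self) -> "Cohort":
        return Cohort(self.weight.copy(), self.height.copy(), self.state.copy(),
                      self.tenure.copy(), self.alive.copy(),
                      self.disc_cost.copy(), self.disc_qaly.copy(),
                      {s: v.copy() for s, v in self.ever.items()})

    # -- summary moments ---------------------------------------------------
    def bmi(self) -> np.ndarray:
        return self.weight / self.height**2

    def mean_weight(self) -> float:
        return float(self.weight.mean())

    def sd_weight(self) -> float:
        return float(self.weight.std(ddof=1))

    def obesity_prevalence(self) -> float:
        return float((self.bmi() >= OBESITY_BMI).mean())

    def state_counts(self) -> np.ndarray:
        return np.bincount(self.state, minlength=len(HealthState))

    # -- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(self.n),
            "weight_kg": self.weight,
            "height_m": self.height,
            "state": [HealthState(s).name.lower() for s in self.state],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        state = np.array([state_from_name(s) for s in df["state"]], dtype=np.int8)
        return cls(df["weight_kg"].to_numpy(), df["height_m"].to_numpy(), state)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path))


def _weight_height_from_z(spec: PopulationSpec, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map a (2, n) standard-normal array through the Gaussian copula."""
    zw = z[0]
    zh = spec.corr * z[0] + math.sqrt(1.0 - spec.corr**2) * z[1]
    weight = np.exp(spec.mean_log_weight + spec.sd_log_weight * zw)
    height = np.clip(spec.mean_height + spec.sd_height * zh, HEIGHT_MIN, HEIGHT_MAX)
    return weight, height


def generate_cohort(spec: PopulationSpec, seed: int) -> Cohort:
    """Draw ``spec.n`` disease-free adults; initial state from baseline BMI."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((2, spec.n))
    weight, height = _weight_height_from_z(spec, z)
    state = classify_bmi(weight, height)
    state = np.atleast_1d(state).astype(np.int8)
    return Cohort(weight, height, state)


def calibrate(targets: CalibrationTargets | None = None, *,
              mean_height: float = 1.68, sd_height: float = 0.10,
              n: int = 20_000, n_check: int = 400_000, seed: int = 1959,
              tol: float = 0.005,
              corr_bounds: tuple[float, float] = (-0.95, 0.95)) -> PopulationSpec:
    """Solve a PopulationSpec that reproduces the calibration targets.

    The log-normal weight parameters come from exact moment matching; the
    weight–height correlation is then found by a Brent root search on the
    obesity prevalence of a fixed n_check-draw standard-normal sample (common
    random numbers make the objective smooth in the correlation).
    """
    targets = targets or CalibrationTargets()
    if not 0.0 < targets.obesity_prev < 1.0:
        raise CalibrationError(
            f"obesity prevalence target must lie in (0, 1), got {targets.obesity_prev}")
    mu, sigma = lognormal_params(targets.mean_weight, targets.sd_weight)
    rng = np.random.default_rng(seed)
    # antithetic pairs halve the Monte-Carlo error of the search objective
    z_half = rng.standard_normal((2, (n_check + 1) // 2))
    z = np.concatenate([z_half, -z_half], axis=1)

    def prevalence(corr: float) -> float:
        spec = PopulationSpec(n=n_check, mean_log_weight=mu, sd_log_weight=sigma,
                              mean_height=mean_height, sd_height=sd_height,
                              corr=corr, targets=targets)
        w, h = _weight_height_from_z(spec, z)
        return float((w / h**2 >= OBESITY_BMI).mean())

    lo, hi = corr_bounds
    f_lo = prevalence(lo) - targets.obesity_prev
    f_hi = prevalence(hi) - targets.obesity_prev
    if f_lo * f_hi > 0:
        raise CalibrationError(
            "could not bracket the obesity prevalence target: prevalence at "
            f"corr={lo} is {f_lo + targets.obesity_prev:.4f}, at corr={hi} is "
            f"{f_hi + targets.obesity_prev:.4f}, target {targets.obesity_prev:.4f}")
    corr = brentq(lambda c: prevalence(c) - targets.obesity_prev, lo, hi, xtol=1e-5)
    achieved = prevalence(corr)
    if abs(achieved - targets.obesity_prev) > tol:
        raise CalibrationError(
            f"calibration reached prevalence {achieved:.4f}, "
            f"target {targets.obesity_prev:.4f} (tolerance {tol})")
    return PopulationSpec(n=n, mean_log_weight=mu, sd_log_weight=sigma,
                          mean_height=mean_height, sd_height=sd_height,
                          corr=corr, targets=targets)
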