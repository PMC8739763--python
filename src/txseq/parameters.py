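"""Model inputs and elementary conversions.

Holds the age-stratified rate table, the retransplant-candidacy schedule,
the scenario configuration (sequence choice plus assumption overrides), and
the uncertainty-analysis settings, together with the rate/probability
conversions used by the transition engine.

All rates are annual event rates per person-year.  Conversions assume a
constant hazard within each age bracket and within each yearly cycle.
"""

from __future__ import annotations

import dataclasses
import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

AGE_MIN = 0
AGE_MAX = 90

#: age-stratified rate fields of a :class:`RateTable`
BRACKET_FIELDS = (
    "dialysis_mortality",
    "graft_mortality",
    "graft_failure_LD",
    "graft_failure_DD",
)

#: scalar transplant-rate fields (per person-waiting-year)
SCALAR_FIELDS = ("tx_rate_DD_pediatric", "tx_rate_DD_adult", "tx_rate_third")

#: USRDS-style default age grouping, half-open [lo, hi)
DEFAULT_BRACKETS = (
    (0, 5), (5, 10), (10, 14), (14, 18), (18, 22), (22, 30),
    (30, 40), (40, 50), (50, 60), (60, 70), (70, 80), (80, 90),
)

SEQUENCES = ("LD-DD", "DD-LD", "DD-DD", "LD-LD")

#: age below which the pediatric deceased-donor transplant rate applies
PEDIATRIC_AGE_LIMIT = 18


class TableValidationError(ValueError):
    """Raised when a rate table violates its structural invariants."""


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------

def rate_to_prob(rate: float) -> float:
    """Convert an annual event rate to a one-year transition probability.

    Uses the constant-hazard relation ``p = 1 - exp(-rate)``.

    Parameters
    ----------
    rate
        Annual events per person-year; must be non-negative.

    Returns
    -------
    float
        Probability in ``[0, 1)`` of at least one event within one cycle.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return -math.expm1(-rate)


def prob5_to_annual_rate(p5: float) -> float:
    """Convert a 5-year failure probability to a constant annual rate.

    Inverse of applying :func:`rate_to_prob` over five years:
    ``rate = -ln(1 - p5) / 5``.
    """
    if not 0.0 <= p5 < 1.0:
        raise ValueError(f"5-year probability must be in [0, 1), got {p5}")
    return -math.log1p(-p5) / 5.0


def competing_risk_probs(
    rates: Sequence[float],
) -> tuple[list[float], float]:
    """Allocate one cycle's event probability among competing events.

    Event ``i`` with rate ``r_i`` receives probability
    ``(r_i / R) * (1 - exp(-R))`` where ``R`` is the total rate
    (proportional-hazards allocation; order-invariant).

    Returns
    -------
    (probs, stay)
        Per-event probabilities and the complementary stay-probability;
        together they sum to 1 exactly.
    """
    rates = [float(r) for r in rates]
    for r in rates:
        if r < 0:
            raise ValueError(f"rates must be non-negative, got {r}")
    total = sum(rates)
    if total == 0.0:
        return [0.0] * len(rates), 1.0
    p_any = -math.expm1(-total)
    probs = [r / total * p_any for r in rates]
    return probs, 1.0 - sum(probs)


# ---------------------------------------------------------------------------
# Rate table
# ---------------------------------------------------------------------------

@dataclass
class RateTable:
    """Age-stratified annual event rates driving the transition model.

    ``age_brackets`` are half-open integer intervals ``[lo, hi)`` that must
    be disjoint, contiguous, and cover ``[0, 90)``.  Each bracket field has
    one value per bracket; transplant rates are scalars (the pediatric rate
    applies below age 18, the adult rate at and above).
    """

    age_brackets: tuple[tuple[int, int], ...]
    dialysis_mortality: np.ndarray
    graft_mortality: np.ndarray
    graft_failure_LD: np.ndarray
    graft_failure_DD: np.ndarray
    tx_rate_DD_pediatric: float = 0.40
    tx_rate_DD_adult: float = 0.15
    tx_rate_third: float = 0.12

    def __post_init__(self) -> None:
        self.age_brackets = tuple((int(lo), int(hi)) for lo, hi in self.age_brackets)
        for name in BRACKET_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in SCALAR_FIELDS:
            setattr(self, name, float(getattr(self, name)))
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        brackets = self.age_brackets
        if not brackets:
            raise TableValidationError("rate table has no age brackets")
        if brackets[0][0] != AGE_MIN:
            raise TableValidationError(
                f"age brackets must start at {AGE_MIN}, got {brackets[0][0]}"
            )
        if brackets[-1][1] != AGE_MAX:
            raise TableValidationError(
                f"age brackets must end at {AGE_MAX}, got {brackets[-1][1]}"
            )
        for (lo, hi), (nlo, _) in zip(brackets, brackets[1:]):
            if hi != nlo:
                raise TableValidationError(
                    f"age brackets must be contiguous: gap between {hi} and {nlo}"
                )
        for lo, hi in brackets:
            if lo >= hi:
                raise TableValidationError(f"empty age bracket [{lo}, {hi})")
        n = len(brackets)
        for name in BRACKET_FIELDS:
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise TableValidationError(
                    f"{name} must have one value per bracket "
                    f"({n}), got shape {arr.shape}"
                )
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise TableValidationError(f"{name} has negative or non-finite values")
        for name in SCALAR_FIELDS:
            if getattr(self, name) < 0:
                raise TableValidationError(f"{name} must be non-negative")

    # -- access -------------------------------------------------------------

    def bracket_index(self, age: float) -> int:
        if not AGE_MIN <= age < AGE_MAX:
            raise ValueError(f"age {age} outside covered range [{AGE_MIN}, {AGE_MAX})")
        los = [lo for lo, _ in self.age_brackets]
        return bisect_right(los, age) - 1

    def lookup(self, field: str, age: float) -> float:
        """Annual rate of ``field`` at ``age`` (half-open bracket convention)."""
        if field in SCALAR_FIELDS:
            return getattr(self, field)
        if field not in BRACKET_FIELDS:
            raise KeyError(f"unknown rate field {field!r}")
        return float(getattr(self, field)[self.bracket_index(age)])

    def tx_rate_DD(self, age: float) -> float:
        """Waiting-list deceased-donor transplant rate at ``age``."""
        if age < PEDIATRIC_AGE_LIMIT:
            return self.tx_rate_DD_pediatric
        return self.tx_rate_DD_adult

    def per_age(self, field: str) -> np.ndarray:
        """Expand a bracket field to a length-90 per-integer-age vector."""
        out = np.empty(AGE_MAX - AGE_MIN)
        arr = getattr(self, field)
        for i, (lo, hi) in enumerate(self.age_brackets):
            out[lo:hi] = arr[i]
        return out

    def copy(self) -> "RateTable":
        return RateTable(
            age_brackets=self.age_brackets,
            **{f: getattr(self, f).copy() for f in BRACKET_FIELDS},
            **{f: getattr(self, f) for f in SCALAR_FIELDS},
        )


def lookup_rate(table: RateTable, field: str, age: float) -> float:
    """Annual rate for ``field`` at ``age`` from ``table``."""
    return table.lookup(field, age)


# ---------------------------------------------------------------------------
# Candidacy schedule
# ---------------------------------------------------------------------------

#: anchor points (age, probability of retransplant candidacy)
DEFAULT_CANDIDACY_ANCHORS = (
    (30, 1.0), (50, 0.80), (60, 0.30), (70, 0.05), (80, 0.0),
)


@dataclass(frozen=True)
class CandidacySchedule:
    """Age-dependent probability of medical eligibility for retransplant.

    Piecewise-linear between anchors, flat outside the anchored range
    (so by default 1.0 at and below age 30 and 0.0 at and above 80).
    """

    anchors: tuple[tuple[float, float], ...] = DEFAULT_CANDIDACY_ANCHORS
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.interpolation != "linear":
            raise ValueError(f"unsupported interpolation {self.interpolation!r}")
        object.__setattr__(
            self,
            "anchors",
            tuple((float(a), float(p)) for a, p in self.anchors),
        )
        ages = [a for a, _ in self.anchors]
        probs = [p for _, p in self.anchors]
        if not ages:
            raise ValueError("candidacy schedule needs at least one anchor")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("anchor ages must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("anchor probabilities must be in [0, 1]")
        if any(q > p for p, q in zip(probs, probs[1:])):
            raise ValueError("candidacy must be non-increasing with age")

    def probability(self, age: float, multiplier: float = 1.0) -> float:
        """Candidacy probability at ``age``, scaled by ``multiplier``."""
        if not 0 <= age <= 120:
            raise ValueError(f"age {age} outside [0, 120]")
        if not 0.0 <= multiplier <= 1.0:
            raise ValueError(f"multiplier must be in [0, 1], got {multiplier}")
        ages = [a for a, _ in self.anchors]
        probs = [p for _, p in self.anchors]
        return float(np.interp(age, ages, probs)) * multiplier


def candidacy_at_age(
    age: float, schedule: CandidacySchedule, multiplier: float = 1.0
) -> float:
    """Probability of retransplant candidacy at ``age`` under ``schedule``."""
    return schedule.probability(age, multiplier)


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One transplant-sequence option plus all assumption overrides.

    Defaults reproduce the baseline assumptions: 10% chance the live donor
    is unavailable at the time of first graft failure, preemptive
    retransplant probabilities of 20% (LD) and 15% (DD), full candidacy
    schedule, third (deceased-donor, never preemptive) transplant enabled.
    """

    sequence: str
    start_age: int
    horizon_age: int = 90
    ld_available_prob: float = 0.90
    preemptive_prob_LD: float = 0.20
    preemptive_prob_DD: float = 0.15
    force_preemptive: bool = False
    candidacy_multiplier: float = 1.0
    third_tx_enabled: bool = True
    pediatric_rate_override: float | None = None
    young_mortality_override: bool = False
    ld_failure_ratio_override: float | None = None
    half_cycle_correction: bool = False
    # probability an awaited live donor is transplanted in each waiting cycle
    awaiting_ld_tx_prob: float = 1.0
    # re-evaluate candidacy each cycle spent waiting (off: evaluated once,
    # at the age of graft failure)
    recheck_candidacy: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise ValueError(
                f"unknown sequence {self.sequence!r}; expected one of {SEQUENCES}"
            )
        if not 3 <= self.start_age <= 25:
            raise ValueError(
                f"start_age must be in [3, 25], got {self.start_age}"
            )
        if self.start_age >= self.horizon_age:
            raise ValueError("start_age must be below horizon_age")
        if self.horizon_age > AGE_MAX:
            raise ValueError(f"horizon_age cannot exceed {AGE_MAX}")
        for name in (
            "ld_available_prob",
            "preemptive_prob_LD",
            "preemptive_prob_DD",
            "candidacy_multiplier",
            "awaiting_ld_tx_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pediatric_rate_override is not None and self.pediatric_rate_override < 0:
            raise ValueError("pediatric_rate_override must be non-negative")
        if self.ld_failure_ratio_override is not None and self.ld_failure_ratio_override < 0:
            raise ValueError("ld_failure_ratio_override must be non-negative")

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)


def apply_overrides(table: RateTable, config: ScenarioConfig) -> RateTable:
    """Return a copy of ``table`` with the config's rate substitutions applied.

    Touches only the targeted fields and age brackets:

    - ``pediatric_rate_override`` replaces the pediatric DD transplant rate;
    - ``young_mortality_override`` sets waiting-list mortality for brackets
      intersecting ages [3, 10) to the value of the bracket containing 10;
    - ``ld_failure_ratio_override`` sets LD graft-failure rates to
      ``ratio * DD`` for brackets intersecting ages [10, 25).
    """
    new = table.copy()
    if config.pediatric_rate_override is not None:
        new.tx_rate_DD_pediatric = float(config.pediatric_rate_override)
    if config.young_mortality_override:
        ref = table.lookup("dialysis_mortality", 10)
        for i, (lo, hi) in enumerate(new.age_brackets):
            if lo < 10 and hi > 3:
                new.dialysis_mortality[i] = ref
    if config.ld_failure_ratio_override is not None:
        ratio = float(config.ld_failure_ratio_override)
        for i, (lo, hi) in enumerate(new.age_brackets):
            if lo < 25 and hi > 10:
                new.graft_failure_LD[i] = ratio * new.graft_failure_DD[i]
    return new


# ---------------------------------------------------------------------------
# Uncertainty settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertaintySpec:
    """Settings for the log-normal probabilistic sensitivity analysis."""

    n_trials: int = 1000
    sigma: float = 0.10
    seed: int = 0
    perturbed_fields: tuple[str, ...] = BRACKET_FIELDS

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        unknown = set(self.perturbed_fields) - set(BRACKET_FIELDS)
        if unknown:
            raise ValueError(f"unknown perturbed fields: {sorted(unknown)}")
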