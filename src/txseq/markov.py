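"""State space and deterministic yearly-cycle cohort solver.

The cohort model propagates a probability distribution over health states
from the starting age to the horizon (age 90 by default), accruing expected
life-years and the expected number of deceased-donor kidneys used.

States (see :class:`ModelState`):

- ``PRE_TX1_WAITLIST`` — on dialysis awaiting the first transplant
  (deceased-donor-first sequences only);
- ``TX_FUNCTIONING`` — alive with a functioning graft (transplant 1–3,
  live- or deceased-donor);
- ``POST_FAIL_AWAITING`` — graft failed, candidate for the next transplant,
  on dialysis awaiting it;
- ``DIALYSIS_NO_FURTHER_TX`` — graft failed with no further transplant
  option (not a candidate, or all transplants exhausted);
- ``DEAD`` — absorbing.

Within a cycle, death-with-function and graft failure (or death-on-dialysis
and transplant receipt) compete under proportional-hazards allocation.  At
the moment of graft failure the failing mass splits by candidacy at the
current age, then (second transplant only) by live-donor availability and
by preemptive-versus-waitlisted retransplant.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .parameters import (
    CandidacySchedule,
    RateTable,
    ScenarioConfig,
    apply_overrides,
    competing_risk_probs,
    rate_to_prob,
)


class Stage(str, Enum):
    WAITLIST = "PRE_TX1_WAITLIST"
    TX = "TX_FUNCTIONING"
    AWAIT = "POST_FAIL_AWAITING"
    NO_TX = "DIALYSIS_NO_FURTHER_TX"
    DEAD = "DEAD"


@dataclass(frozen=True)
class ModelState:
    """One health state of the transplant-sequencing model.

    ``tx_index`` counts transplants received so far; ``graft_source`` is the
    source of the currently functioning graft ("none" off-graft);
    ``next_source`` is the source awaited in ``POST_FAIL_AWAITING``.
    """

    stage: Stage
    tx_index: int = 0
    graft_source: str = "none"
    next_source: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.tx_index <= 3:
            raise ValueError("tx_index must be in 0..3")
        if self.stage is Stage.TX and self.graft_source == "none":
            raise ValueError("functioning-graft state needs a graft source")
        if self.stage is Stage.WAITLIST and self.tx_index != 0:
            raise ValueError("pre-first-transplant waitlist requires tx_index 0")

    def __str__(self) -> str:  # compact label for reports
        if self.stage is Stage.TX:
            return f"TX{self.tx_index}_{self.graft_source}"
        if self.stage is Stage.AWAIT:
            return f"AWAIT{self.tx_index + 1}_{self.next_source}"
        return self.stage.value


DEAD = ModelState(Stage.DEAD)
NO_TX = ModelState(Stage.NO_TX)
WAITLIST = ModelState(Stage.WAITLIST)


def _tx(index: int, source: str) -> ModelState:
    return ModelState(Stage.TX, index, source)


def _await(received: int, next_source: str) -> ModelState:
    return ModelState(Stage.AWAIT, received, "none", next_source)


def _first_source(config: ScenarioConfig) -> str:
    return "LD" if config.sequence.startswith("LD") else "DD"


def _second_sources(config: ScenarioConfig) -> tuple[tuple[str, float], ...]:
    """Possible second-transplant sources with their split weights.

    For LD-second sequences the live donor is available with probability
    ``ld_available_prob``, resolved once at the moment of first graft
    failure; otherwise the pathway continues deceased-donor.
    """
    if config.sequence in ("LD-DD", "DD-DD"):
        return (("DD", 1.0),)
    q = config.ld_available_prob
    out: list[tuple[str, float]] = []
    if q > 0:
        out.append(("LD", q))
    if q < 1:
        out.append(("DD", 1.0 - q))
    return tuple(out)


def _preempt_prob(config: ScenarioConfig, source: str) -> float:
    if config.force_preemptive:
        return 1.0
    if source == "LD":
        return config.preemptive_prob_LD
    return config.preemptive_prob_DD


def build_state_space(config: ScenarioConfig) -> tuple[ModelState, ...]:
    """Enumerate the states reachable under ``config``, in a fixed order."""
    states: list[ModelState] = []
    first = _first_source(config)
    if first == "DD":
        states.append(WAITLIST)
    states.append(_tx(1, first))
    seconds = _second_sources(config)
    for src, _ in seconds:
        if _preempt_prob(config, src) < 1.0:
            states.append(_await(1, src))
    for src, _ in seconds:
        states.append(_tx(2, src))
    if config.third_tx_enabled:
        states.append(_await(2, "DD"))
        states.append(_tx(3, "DD"))
    states.append(NO_TX)
    states.append(DEAD)
    return tuple(states)


def _failure_split(
    tx_index: int,
    age: float,
    config: ScenarioConfig,
    schedule: CandidacySchedule,
) -> dict[ModelState, float]:
    """Destination weights (summing to 1) for mass whose graft fails at ``age``."""
    c = schedule.probability(age, config.candidacy_multiplier)
    out: dict[ModelState, float] = defaultdict(float)
    if c < 1.0:
        out[NO_TX] += 1.0 - c
    if c == 0.0:
        return dict(out)
    if tx_index == 1:
        for src, w in _second_sources(config):
            p_pre = _preempt_prob(config, src)
            if p_pre > 0:
                out[_tx(2, src)] += c * w * p_pre
            if p_pre < 1:
                out[_await(1, src)] += c * w * (1.0 - p_pre)
    elif tx_index == 2 and config.third_tx_enabled:
        # third transplant: always deceased-donor, never preemptive
        out[_await(2, "DD")] += c
    else:
        out[NO_TX] += c
    return dict(out)


def transition_row(
    state: ModelState,
    age: float,
    table: RateTable,
    config: ScenarioConfig,
    schedule: CandidacySchedule,
) -> dict[ModelState, float]:
    """One-cycle transition distribution out of ``state`` at ``age``.

    ``table`` is used as given — scenario rate substitutions are applied by
    :func:`solve_cohort` before rows are assembled.
    """
    if state.stage is Stage.DEAD:
        return {DEAD: 1.0}

    if state.stage is Stage.NO_TX:
        p_die = rate_to_prob(table.lookup("dialysis_mortality", age))
        return {DEAD: p_die, NO_TX: 1.0 - p_die}

    if state.stage is Stage.WAITLIST:
        (p_die, p_tx), stay = competing_risk_probs(
            [table.lookup("dialysis_mortality", age), table.tx_rate_DD(age)]
        )
        return {DEAD: p_die, _tx(1, "DD"): p_tx, WAITLIST: stay}

    if state.stage is Stage.TX:
        fail_field = (
            "graft_failure_LD" if state.graft_source == "LD" else "graft_failure_DD"
        )
        (p_die, p_fail), stay = competing_risk_probs(
            [table.lookup("graft_mortality", age), table.lookup(fail_field, age)]
        )
        row: dict[ModelState, float] = defaultdict(float)
        row[DEAD] += p_die
        row[state] += stay
        if p_fail > 0:
            for dest, w in _failure_split(
                state.tx_index, age, config, schedule
            ).items():
                row[dest] += p_fail * w
        return dict(row)

    # POST_FAIL_AWAITING
    if state.next_source == "LD":
        # an awaited live donor is assumed faster than the waiting list:
        # received next cycle with probability awaiting_ld_tx_prob
        p_die = rate_to_prob(table.lookup("dialysis_mortality", age))
        p_tx = (1.0 - p_die) * config.awaiting_ld_tx_prob
        row = {
            DEAD: p_die,
            _tx(state.tx_index + 1, "LD"): p_tx,
            state: 1.0 - p_die - p_tx,
        }
    else:
        rate = (
            table.tx_rate_third if state.tx_index == 2 else table.tx_rate_DD(age)
        )
        (p_die, p_tx), stay = competing_risk_probs(
            [table.lookup("dialysis_mortality", age), rate]
        )
        row = {DEAD: p_die, _tx(state.tx_index + 1, "DD"): p_tx, state: stay}

    if config.recheck_candidacy:
        # optional: lose candidacy while waiting at the hazard implied by
        # the schedule's decline between this age and the next
        c_now = schedule.probability(age, config.candidacy_multiplier)
        c_next = schedule.probability(age + 1, config.candidacy_multiplier)
        if c_now > 0:
            drop = max(0.0, 1.0 - c_next / c_now)
            stay_mass = row.get(state, 0.0)
            if drop > 0 and stay_mass > 0:
                row[state] = stay_mass * (1.0 - drop)
                row[NO_TX] = row.get(NO_TX, 0.0) + stay_mass * drop
    return row


def transition_matrix(
    states: tuple[ModelState, ...],
    index: dict[ModelState, int],
    age: float,
    table: RateTable,
    config: ScenarioConfig,
    schedule: CandidacySchedule,
) -> np.ndarray:
    """Row-stochastic one-cycle matrix over ``states`` at ``age``."""
    n = len(states)
    P = np.zeros((n, n))
    for i, s in enumerate(states):
        for dest, p in transition_row(s, age, table, config, schedule).items():
            P[i, index[dest]] += p
    return P


@dataclass
class CohortResult:
    """Deterministic cohort-model output for one scenario."""

    life_years: float
    dd_kidneys_used: float
    occupancy: np.ndarray  # (n_cycles + 1, n_states), rows at cycle starts
    survival_curve: np.ndarray  # (n_cycles + 1,), probability alive
    states: tuple[ModelState, ...]
    start_age: int
    horizon_age: int
    config: ScenarioConfig = field(repr=False, default=None)

    def occupancy_frame(self) -> pd.DataFrame:
        """Tidy per-cycle occupancy: columns cycle, age, state, probability."""
        records = []
        for t in range(self.occupancy.shape[0]):
            for j, s in enumerate(self.states):
                records.append(
                    {
                        "cycle": t,
                        "age": self.start_age + t,
                        "state": str(s),
                        "probability": self.occupancy[t, j],
                    }
                )
        return pd.DataFrame.from_records(records)


def initial_state(config: ScenarioConfig) -> ModelState:
    """Entry state: LD-first sequences start transplanted (no waiting);
    DD-first sequences start on the waiting list."""
    first = _first_source(config)
    if first == "LD":
        return _tx(1, "LD")
    return WAITLIST


def solve_cohort(
    config: ScenarioConfig,
    table: RateTable,
    schedule: CandidacySchedule | None = None,
) -> CohortResult:
    """Propagate the cohort from ``start_age`` to ``horizon_age``.

    A full life-year is accrued for each cycle begun alive (half-cycle
    correction available via ``config.half_cycle_correction``).  Expected
    deceased-donor kidneys are the cumulative probability flux into any
    functioning-DD-graft state.
    """
    if schedule is None:
        schedule = CandidacySchedule()
    tbl = apply_overrides(table, config)
    states = build_state_space(config)
    index = {s: i for i, s in enumerate(states)}
    n_states = len(states)
    dead_i = index[DEAD]
    dd_targets = [
        i for i, s in enumerate(states)
        if s.stage is Stage.TX and s.graft_source == "DD"
    ]

    n_cycles = config.horizon_age - config.start_age
    occ = np.zeros(n_states)
    occ[index[initial_state(config)]] = 1.0

    occupancy = np.empty((n_cycles + 1, n_states))
    survival = np.empty(n_cycles + 1)
    dd_used = 0.0
    for t in range(n_cycles):
        occupancy[t] = occ
        survival[t] = 1.0 - occ[dead_i]
        P = transition_matrix(
            states, index, config.start_age + t, tbl, config, schedule
        )
        for j in dd_targets:
            # inflow from other states only: entering TX_j means a new graft
            dd_used += occ @ P[:, j] - occ[j] * P[j, j]
        occ = occ @ P
    occupancy[n_cycles] = occ
    survival[n_cycles] = 1.0 - occ[dead_i]

    if config.half_cycle_correction:
        life_years = 0.5 * survival[0] + survival[1:n_cycles].sum() + 0.5 * survival[n_cycles]
    else:
        life_years = float(survival[:n_cycles].sum())

    return CohortResult(
        life_years=float(life_years),
        dd_kidneys_used=float(dd_used),
        occupancy=occupancy,
        survival_curve=survival,
        states=states,
        start_age=config.start_age,
        horizon_age=config.horizon_age,
        config=config,
    )


def net_difference(
    result1: CohortResult, result2: CohortResult
) -> tuple[float, float]:
    """(life-years option1 − option2, DD kidneys option2 − option1)."""
    if (result1.start_age, result1.horizon_age) != (
        result2.start_age,
        result2.horizon_age,
    ):
        raise ValueError(
            "results must share start_age and horizon_age to be compared"
        )
    return (
        result1.life_years - result2.life_years,
        result2.dd_kidneys_used - result1.dd_kidneys_used,
    )
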