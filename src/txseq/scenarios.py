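"""Comparison grids: baseline availability triplets, no-live-donor tables,
one-way sensitivity rows, and age sweeps.

Each grid row solves two scenario options on the same rate table and
reports life-years and deceased-donor kidney use per option plus the net
difference (optionally with a Monte Carlo 95% CI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markov import net_difference, solve_cohort
from .microsim import uncertainty_net_difference
from .parameters import (
    CandidacySchedule,
    RateTable,
    ScenarioConfig,
    UncertaintySpec,
)

REPORT_COLUMNS = (
    "start_age", "scenario", "option1", "option2",
    "ly1", "dd1", "ly2", "dd2", "net_ly", "net_dd", "ci_low", "ci_high",
)

DEFAULT_GRID_AGES = (3, 5, 10, 15, 20, 25)

#: default availability sweep; the published range is "the entire range"
AVAILABILITY_GRID = (0.0, 0.25, 0.50, 0.75, 1.0)


@dataclass
class ComparisonReport:
    """Tabular comparison of two options across ages and scenario variants."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REPORT_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"report frame missing columns: {sorted(missing)}")
        self.frame = self.frame.loc[:, list(REPORT_COLUMNS)].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ComparisonReport":
        return cls(pd.read_csv(path))

    def to_text(self) -> str:
        """Aligned plain-text rendering."""
        return self.frame.to_string(
            index=False, float_format=lambda v: f"{v:.3f}"
        )


def compare_options(
    config1: ScenarioConfig,
    config2: ScenarioConfig,
    table: RateTable,
    schedule: CandidacySchedule | None = None,
    spec: UncertaintySpec | None = None,
    scenario: str = "",
) -> dict:
    """One report row: both options solved, net difference, optional CI."""
    r1 = solve_cohort(config1, table, schedule)
    r2 = solve_cohort(config2, table, schedule)
    net_ly, net_dd = net_difference(r1, r2)
    ci_low = ci_high = math.nan
    if spec is not None:
        unc = uncertainty_net_difference(config1, config2, table, schedule, spec)
        ci_low, ci_high = unc.ci_low, unc.ci_high
    return {
        "start_age": config1.start_age,
        "scenario": scenario,
        "option1": config1.sequence,
        "option2": config2.sequence,
        "ly1": r1.life_years,
        "dd1": r1.dd_kidneys_used,
        "ly2": r2.life_years,
        "dd2": r2.dd_kidneys_used,
        "net_ly": net_ly,
        "net_dd": net_dd,
        "ci_low": ci_low,
        "ci_high": ci_high,
    }


def run_baseline_grid(
    ages: Sequence[int] = DEFAULT_GRID_AGES,
    table: RateTable | None = None,
    schedule: CandidacySchedule | None = None,
    spec: UncertaintySpec | None = None,
) -> ComparisonReport:
    """LD-DD versus DD-LD under the three availability variants per age:
    10% unavailable (baseline), always available, always available and
    preemptive."""
    if table is None:
        raise ValueError("a rate table is required")
    rows = []
    for age in ages:
        opt1 = ScenarioConfig("LD-DD", start_age=age)
        variants = (
            ("LD not available 10% of the time", {"ld_available_prob": 0.90}),
            ("LD always available", {"ld_available_prob": 1.0}),
            (
                "LD always available and preemptive",
                {"ld_available_prob": 1.0, "force_preemptive": True},
            ),
        )
        for label, changes in variants:
            opt2 = ScenarioConfig("DD-LD", start_age=age, **changes)
            rows.append(
                compare_options(opt1, opt2, table, schedule, spec, scenario=label)
            )
    return ComparisonReport(pd.DataFrame(rows))


def run_no_ld_grid(
    ages: Sequence[int] = DEFAULT_GRID_AGES,
    table: RateTable | None = None,
    schedule: CandidacySchedule | None = None,
    spec: UncertaintySpec | None = None,
) -> ComparisonReport:
    """LD-DD versus DD-DD (no live donor ever available) per age under
    baseline assumptions, 20% lower candidacy, and no-third-transplant."""
    if table is None:
        raise ValueError("a rate table is required")
    variants = (
        ("baseline assumptions", {}),
        ("20% lower candidacy", {"candidacy_multiplier": 0.8}),
        ("no third transplant", {"third_tx_enabled": False}),
    )
    rows = []
    for age in ages:
        for label, changes in variants:
            opt1 = ScenarioConfig("LD-DD", start_age=age, **changes)
            opt2 = ScenarioConfig("DD-DD", start_age=age, **changes)
            rows.append(
                compare_options(opt1, opt2, table, schedule, spec, scenario=label)
            )
    return ComparisonReport(pd.DataFrame(rows))


def run_sensitivity_suite(
    age: int,
    table: RateTable,
    schedule: CandidacySchedule | None = None,
    spec: UncertaintySpec | None = None,
) -> ComparisonReport:
    """One-way sensitivity rows for LD-DD versus DD-LD at one start age.

    Covers: the live-donor availability sweep, pediatric DD transplant rate
    set to the adult rate, 20% lower candidacy, preemptive probabilities 0
    and 1, young-child waiting-list mortality equalized to ages 10-13, and
    LD graft-failure rates halved relative to DD for ages 10-24.
    """
    rows = []

    def row(label, shared=None, opt2_only=None):
        shared = shared or {}
        opt2_only = opt2_only or {}
        opt1 = ScenarioConfig("LD-DD", start_age=age, **shared)
        opt2 = ScenarioConfig("DD-LD", start_age=age, **shared, **opt2_only)
        rows.append(
            compare_options(opt1, opt2, table, schedule, spec, scenario=label)
        )

    for q in AVAILABILITY_GRID:
        row(f"LD availability {q:.2f}", opt2_only={"ld_available_prob": q})
    row(
        "pediatric DD rate = adult rate",
        shared={"pediatric_rate_override": table.tx_rate_DD_adult},
    )
    row("20% lower candidacy", shared={"candidacy_multiplier": 0.8})
    row(
        "never preemptive",
        shared={"preemptive_prob_LD": 0.0, "preemptive_prob_DD": 0.0},
    )
    row("always preemptive", shared={"force_preemptive": True})
    row(
        "young waiting-list mortality equalized",
        shared={"young_mortality_override": True},
    )
    row(
        "LD failure half of DD, ages 10-24",
        shared={"ld_failure_ratio_override": 0.5},
    )
    return ComparisonReport(pd.DataFrame(rows))


def age_sweep(
    config1: ScenarioConfig,
    config2: ScenarioConfig,
    ages: Iterable[int],
    table: RateTable,
    schedule: CandidacySchedule | None = None,
) -> pd.DataFrame:
    """Evaluate both options at each start age; plottable tidy frame."""
    records = []
    for age in ages:
        c1 = config1.replace(start_age=age)
        c2 = config2.replace(start_age=age)
        r1 = solve_cohort(c1, table, schedule)
        r2 = solve_cohort(c2, table, schedule)
        net_ly, net_dd = net_difference(r1, r2)
        records.append(
            {
                "start_age": age,
                "ly1": r1.life_years,
                "ly2": r2.life_years,
                "net_ly": net_ly,
                "net_dd": net_dd,
            }
        )
    return pd.DataFrame.from_records(records)


def preset_pair(
    name: str, age: int, table: RateTable
) -> tuple[ScenarioConfig, ScenarioConfig]:
    """Named LD-DD/DD-LD option pairs used by the figure-style sweeps.

    - ``baseline``: 10% LD unavailability, default preemption;
    - ``optimal``: LD always available and always preemptive;
    - ``optimal_young_equalized``: optimal plus ages 3-9 waiting-list
      mortality set to the 10-13 bracket;
    - ``optimal_young_equalized_adult_rate``: additionally the pediatric DD
      transplant rate is set to the adult rate;
    - ``optimal_ld_failure_halved``: optimal plus LD graft-failure rates at
      half the DD rates for ages 10-24.
    """
    shared: dict = {}
    opt2: dict = {}
    if name == "baseline":
        opt2 = {"ld_available_prob": 0.90}
    elif name == "optimal":
        opt2 = {"ld_available_prob": 1.0, "force_preemptive": True}
    elif name == "optimal_young_equalized":
        shared = {"young_mortality_override": True}
        opt2 = {"ld_available_prob": 1.0, "force_preemptive": True}
    elif name == "optimal_young_equalized_adult_rate":
        shared = {
            "young_mortality_override": True,
            "pediatric_rate_override": table.tx_rate_DD_adult,
        }
        opt2 = {"ld_available_prob": 1.0, "force_preemptive": True}
    elif name == "optimal_ld_failure_halved":
        shared = {"ld_failure_ratio_override": 0.5}
        opt2 = {"ld_available_prob": 1.0, "force_preemptive": True}
    else:
        raise ValueError(f"unknown preset {name!r}")
    c1 = ScenarioConfig("LD-DD", start_age=age, **shared)
    c2 = ScenarioConfig("DD-LD", start_age=age, **shared, **opt2)
    return c1, c2


PRESETS = (
    "baseline",
    "optimal",
    "optimal_young_equalized",
    "optimal_young_equalized_adult_rate",
    "optimal_ld_failure_halved",
)
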