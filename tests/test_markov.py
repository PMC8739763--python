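import math

import numpy as np
import pytest

from txseq.markov import (
    DEAD,
    NO_TX,
    WAITLIST,
    ModelState,
    Stage,
    build_state_space,
    initial_state,
    net_difference,
    solve_cohort,
    transition_row,
)
from txseq.parameters import CandidacySchedule, ScenarioConfig
from txseq.synthetic import GeneratorSpec, generate_rate_tables


def cfg(sequence="LD-DD", start_age=5, **kw):
    return ScenarioConfig(sequence, start_age=start_age, **kw)


class TestStateSpace:
    def test_no_third_transplant_states_when_disabled(self):
        states = build_state_space(cfg("DD-DD", third_tx_enabled=False))
        assert all(s.tx_index < 3 for s in states)

    def test_no_ld_second_states_for_dd_dd(self):
        states = build_state_space(cfg("DD-DD"))
        assert not any(
            s.graft_source == "LD" or s.next_source == "LD" for s in states
        )

    def test_single_dead_state(self):
        for seq in ("LD-DD", "DD-LD", "DD-DD", "LD-LD"):
            states = build_state_space(cfg(seq))
            assert sum(1 for s in states if s.stage is Stage.DEAD) == 1

    def test_deterministic_ordering(self):
        c = cfg("DD-LD")
        assert build_state_space(c) == build_state_space(c)

    def test_ld_first_starts_transplanted(self):
        assert initial_state(cfg("LD-DD")) == ModelState(Stage.TX, 1, "LD")
        assert initial_state(cfg("LD-LD")) == ModelState(Stage.TX, 1, "LD")

    def test_dd_first_starts_on_waitlist(self):
        assert initial_state(cfg("DD-LD")) is WAITLIST
        assert initial_state(cfg("DD-DD")) is WAITLIST
        states = build_state_space(cfg("DD-LD"))
        assert states[0] is WAITLIST

    def test_availability_edge_prunes_sources(self):
        full = build_state_space(cfg("DD-LD", ld_available_prob=1.0))
        assert not any(s.next_source == "DD" and s.tx_index == 1 for s in full)
        none = build_state_space(cfg("DD-LD", ld_available_prob=0.0))
        assert not any(
            s.graft_source == "LD" or s.next_source == "LD" for s in none
        )

    def test_invalid_state_combinations_rejected(self):
        with pytest.raises(ValueError):
            ModelState(Stage.TX, 1, "none")
        with pytest.raises(ValueError):
            ModelState(Stage.WAITLIST, 1)
        with pytest.raises(ValueError):
            ModelState(Stage.TX, 4, "LD")


class TestTransitionRow:
    def test_dead_is_absorbing(self, fixture_table, schedule):
        row = transition_row(DEAD, 40, fixture_table, cfg(), schedule)
        assert row == {DEAD: 1.0}

    def test_rows_sum_to_one(self, fixture_table, schedule):
        for seq in ("LD-DD", "DD-LD", "DD-DD", "LD-LD"):
            c = cfg(seq)
            for state in build_state_space(c):
                for age in (3, 10, 17, 18, 35, 62, 81, 89):
                    row = transition_row(state, age, fixture_table, c, schedule)
                    assert abs(sum(row.values()) - 1.0) < 1e-12
                    assert all(p >= 0 for p in row.values())

    def test_zero_table_keeps_mass_except_ld_receipt(self, zero_table, schedule):
        c = cfg("DD-LD")
        for state in build_state_space(c):
            row = transition_row(state, 30, zero_table, c, schedule)
            if state.stage is Stage.AWAIT and state.next_source == "LD":
                dest = ModelState(Stage.TX, state.tx_index + 1, "LD")
                assert row == {DEAD: 0.0, dest: 1.0, state: 0.0}
            else:
                assert row.get(state, 0.0) == 1.0

    def test_pediatric_adult_transplant_rate_switch(self, fixture_table, schedule):
        c = cfg("DD-LD")
        tx1 = ModelState(Stage.TX, 1, "DD")
        row17 = transition_row(WAITLIST, 17, fixture_table, c, schedule)
        row18 = transition_row(WAITLIST, 18, fixture_table, c, schedule)
        # marginal one-year transplant probabilities at the pure rates
        assert row17[tx1] <= 1 - math.exp(-0.40)
        assert row18[tx1] <= 1 - math.exp(-0.15)
        # with competing mortality switched off the marginals are exact
        lone = fixture_table.copy()
        lone.dialysis_mortality[:] = 0.0
        row17 = transition_row(WAITLIST, 17, lone, c, schedule)
        row18 = transition_row(WAITLIST, 18, lone, c, schedule)
        assert row17[tx1] == pytest.approx(1 - math.exp(-0.40), abs=1e-12)
        assert row18[tx1] == pytest.approx(1 - math.exp(-0.15), abs=1e-12)

    def test_noncandidate_mass_goes_to_no_further_tx(self, fixture_table, schedule):
        # at age 80+ candidacy is 0: all failing mass lands in NO_TX
        c = cfg("LD-DD")
        state = ModelState(Stage.TX, 1, "LD")
        row = transition_row(state, 82, fixture_table, c, schedule)
        assert set(row) == {DEAD, state, NO_TX}

    def test_preemptive_split_probabilities(self, fixture_table, schedule):
        c = cfg("DD-LD")
        state = ModelState(Stage.TX, 1, "DD")
        row = transition_row(state, 20, fixture_table, c, schedule)
        tx2_ld = ModelState(Stage.TX, 2, "LD")
        await_ld = ModelState(Stage.AWAIT, 1, "none", "LD")
        # LD branch gets availability 0.9; preemptive fraction 0.20 of it
        assert row[tx2_ld] / (row[tx2_ld] + row[await_ld]) == pytest.approx(0.20)


class TestSolveCohort:
    def test_zero_rates_full_life_years(self, zero_table, schedule):
        for seq in ("LD-DD", "DD-LD", "DD-DD", "LD-LD"):
            r = solve_cohort(cfg(seq, start_age=25), zero_table, schedule)
            assert r.life_years == pytest.approx(65.0, abs=1e-12)

    def test_immortal_ld_first_uses_no_dd_kidneys(self, zero_table, schedule):
        r = solve_cohort(cfg("LD-DD", start_age=25), zero_table, schedule)
        assert r.dd_kidneys_used == 0.0

    def test_extreme_dialysis_mortality_limits_dd_first(self, zero_table, schedule):
        table = zero_table.copy()
        table.dialysis_mortality[:] = 1e9
        r = solve_cohort(cfg("DD-LD", start_age=5), table, schedule)
        # everyone begins on dialysis and dies in the first cycle
        assert r.life_years == pytest.approx(1.0, abs=1e-9)

    def test_mass_conservation(self, fixture_table, schedule):
        for seq in ("LD-DD", "DD-LD"):
            r = solve_cohort(cfg(seq, start_age=3), fixture_table, schedule)
            sums = r.occupancy.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_life_years_bounded_by_horizon(self, fixture_table, schedule):
        r = solve_cohort(cfg("DD-DD", start_age=10), fixture_table, schedule)
        assert 0 < r.life_years <= 80.0

    def test_life_years_equals_survival_sum(self, fixture_table, schedule):
        r = solve_cohort(cfg("LD-DD", start_age=10), fixture_table, schedule)
        assert r.life_years == pytest.approx(r.survival_curve[:-1].sum())

    def test_half_cycle_correction_relation(self, fixture_table, schedule):
        full = solve_cohort(cfg("LD-DD", start_age=10), fixture_table, schedule)
        half = solve_cohort(
            cfg("LD-DD", start_age=10, half_cycle_correction=True),
            fixture_table,
            schedule,
        )
        expected = full.life_years - 0.5 * (1.0 - full.survival_curve[-1])
        assert half.life_years == pytest.approx(expected)

    def test_dd_kidneys_within_bounds(self, fixture_table, schedule):
        for seq in ("LD-DD", "DD-LD", "DD-DD", "LD-LD"):
            r = solve_cohort(cfg(seq, start_age=5), fixture_table, schedule)
            assert 0.0 <= r.dd_kidneys_used <= 3.0

    def test_occupancy_frame_is_tidy(self, fixture_table, schedule):
        r = solve_cohort(cfg("LD-DD", start_age=20), fixture_table, schedule)
        frame = r.occupancy_frame()
        assert set(frame.columns) == {"cycle", "age", "state", "probability"}
        assert frame["cycle"].max() == 70
        per_cycle = frame.groupby("cycle")["probability"].sum()
        np.testing.assert_allclose(per_cycle, 1.0, atol=1e-9)


class TestMonotonicity:
    @pytest.mark.parametrize(
        "field",
        ["dialysis_mortality", "graft_mortality", "graft_failure_LD",
         "graft_failure_DD"],
    )
    def test_raising_rates_never_gains_life_years(
        self, random_tables, schedule, field
    ):
        for table in random_tables:
            worse = table.copy()
            setattr(worse, field, getattr(worse, field) * 1.5)
            for seq in ("LD-DD", "DD-LD"):
                base = solve_cohort(cfg(seq, start_age=10), table, schedule)
                hit = solve_cohort(cfg(seq, start_age=10), worse, schedule)
                assert hit.life_years <= base.life_years + 1e-12

    def test_ld_availability_monotone(self, fixture_table, schedule):
        previous = -np.inf
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            r = solve_cohort(
                cfg("DD-LD", start_age=10, ld_available_prob=q),
                fixture_table,
                schedule,
            )
            assert r.life_years >= previous - 1e-12
            previous = r.life_years

    def test_sequence_dominance(self, random_tables, schedule):
        # LD failure <= DD failure holds by construction for generated tables
        for table in random_tables:
            for age in (5, 20):
                ld_ld = solve_cohort(cfg("LD-LD", start_age=age), table, schedule)
                ld_dd = solve_cohort(cfg("LD-DD", start_age=age), table, schedule)
                dd_dd = solve_cohort(cfg("DD-DD", start_age=age), table, schedule)
                assert ld_ld.life_years >= ld_dd.life_years - 1e-9
                assert ld_dd.life_years >= dd_dd.life_years - 1e-9

    def test_dd_first_uses_more_dd_kidneys(self, random_tables, schedule):
        for table in random_tables:
            for age in (3, 15, 25):
                r1 = solve_cohort(cfg("LD-DD", start_age=age), table, schedule)
                r2 = solve_cohort(cfg("DD-LD", start_age=age), table, schedule)
                assert r2.dd_kidneys_used > r1.dd_kidneys_used


class TestNetDifference:
    def test_identical_results_zero(self, fixture_table, schedule):
        r = solve_cohort(cfg("LD-DD", start_age=5), fixture_table, schedule)
        assert net_difference(r, r) == (0.0, 0.0)

    def test_antisymmetry(self, fixture_table, schedule):
        r1 = solve_cohort(cfg("LD-DD", start_age=5), fixture_table, schedule)
        r2 = solve_cohort(cfg("DD-LD", start_age=5), fixture_table, schedule)
        ly, dd = net_difference(r1, r2)
        ly_swapped, dd_swapped = net_difference(r2, r1)
        assert ly == -ly_swapped
        assert dd == -dd_swapped

    def test_mismatched_start_age_rejected(self, fixture_table, schedule):
        r1 = solve_cohort(cfg("LD-DD", start_age=5), fixture_table, schedule)
        r2 = solve_cohort(cfg("DD-LD", start_age=6), fixture_table, schedule)
        with pytest.raises(ValueError):
            net_difference(r1, r2)

    def test_positive_net_at_key_ages(self, fixture_table, schedule):
        for age in (3, 5, 20, 25):
            r1 = solve_cohort(cfg("LD-DD", start_age=age), fixture_table, schedule)
            r2 = solve_cohort(cfg("DD-LD", start_age=age), fixture_table, schedule)
            ly, _ = net_difference(r1, r2)
            assert ly > 0
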