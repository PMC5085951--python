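import numpy as np
import pandas as pd
import pytest

from thacea.markov import (ENGINE_STATES, ParameterConflictError,
                           build_transition_row, discount_factor,
                           engine_transition_row, run_cohort, run_microsim,
                           transition_matrix)
from thacea.parameters import HealthState, life_table_from_frame


def step_life_table(death_age: int, max_age: int = 110):
    """qx = 0 below ``death_age``, 1 at and above it (both genders)."""
    rows = []
    for g in ("M", "F"):
        for a in range(0, max_age + 1):
            rows.append({"age": a, "gender": g,
                         "qx": 1.0 if a >= death_age else 0.0})
    return life_table_from_frame(pd.DataFrame(rows), max_age=max_age)


def equalized_arms(params):
    """Parameters under which surgery changes nothing relative to no surgery."""
    p = params.copy()
    p.oa_progression_prob = 0.0
    for k in p.perioperative_tha_mortality:
        p.perioperative_tha_mortality[k] = 0.0
    p.perioperative_revision_mortality = {"lt75": 0.0, "ge75": 0.0}
    for k in p.first_revision_rates:
        p.first_revision_rates[k] = 0.0
    for k in p.second_revision_rates:
        p.second_revision_rates[k] = 0.0
    u = p.utilities["end_stage_oa"]
    p.utilities["initial_post_tha"] = dict(u)
    p.utilities["successful_tha"] = dict(u)
    c = p.annual_costs["end_stage_oa"]
    p.annual_costs["initial_post_tha"] = c
    p.annual_costs["successful_tha"] = c
    return p


class TestDiscountFactor:
    @pytest.mark.parametrize("t,r,expected", [
        (0, 0.03, 1.0), (5, 0.0, 1.0), (1, 0.03, 1 / 1.03),
    ])
    def test_values(self, t, r, expected):
        assert discount_factor(t, r) == pytest.approx(expected)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -1.0)


class TestTransitionRows:
    def test_dead_is_absorbing(self, params, life_table):
        row = build_transition_row(HealthState.DEAD, "THA", 70, "M", 3,
                                   params, life_table)
        assert row[HealthState.DEAD] == 1.0
        assert sum(row.values()) == pytest.approx(1.0)

    def test_end_stage_three_way_split(self, params, life_table):
        q = life_table.prob_death(60, "F")
        row = build_transition_row(HealthState.END_STAGE_OA, "nonoperative",
                                   60, "F", 0, params, life_table)
        assert row[HealthState.END_STAGE_OA] == pytest.approx((1 - q) * (1 - 0.041))
        assert row[HealthState.MORE_SEVERE_OA] == pytest.approx((1 - q) * 0.041)
        assert row[HealthState.DEAD] == pytest.approx(q)

    def test_nonsurgery_alias_of_end_stage(self, params, life_table):
        a = build_transition_row(HealthState.NONSURGERY, "nonoperative",
                                 60, "F", 0, params, life_table)
        b = build_transition_row(HealthState.END_STAGE_OA, "nonoperative",
                                 60, "F", 0, params, life_table)
        assert a == b

    def test_surgical_death_combines_with_natural(self, params, life_table):
        q_nat = life_table.prob_death(60, "M")
        q_surg = params.periop_tha_mortality(60, "M")
        row = build_transition_row(HealthState.INITIAL_POST_THA, "THA",
                                   60, "M", 0, params, life_table)
        combined = 1 - (1 - q_nat) * (1 - q_surg)
        # plus revision perioperative deaths among early-revised survivors
        rates = sum(params.first_revision_rate("early", c, 60, "M")
                    for c in ("aseptic", "infection"))
        extra = (1 - combined) * rates * params.periop_revision_mortality(60)
        assert row[HealthState.DEAD] == pytest.approx(combined + extra)

    def test_revision_mortality_doubles_past_75(self, params):
        lt = step_life_table(death_age=110)
        # with natural mortality zeroed, the death mass entering a revision
        # year is exactly rate x perioperative revision mortality
        for age, q_rev in ((70, 0.003), (80, 0.012)):
            row = build_transition_row(HealthState.POST_FIRST_REVISION_EARLY,
                                       "THA", age, "M", 0, params, lt)
            rate = sum(params.second_revision_rate("early", c)
                       for c in ("aseptic", "infection"))
            assert row[HealthState.DEAD] == pytest.approx(rate * q_rev)

    def test_second_revision_reachable_only_from_post_first(self, params, life_table):
        sources = {
            HealthState.END_STAGE_OA: "nonoperative",
            HealthState.MORE_SEVERE_OA: "nonoperative",
            HealthState.INITIAL_POST_THA: "THA",
            HealthState.SUCCESSFUL_THA: "THA",
            HealthState.POST_SECOND_REVISION: "THA",
        }
        for state, arm in sources.items():
            row = build_transition_row(state, arm, 65, "F", 1,
                                       params, life_table)
            if state is HealthState.POST_SECOND_REVISION:
                continue
            assert row[HealthState.POST_SECOND_REVISION] == 0.0
        for state in (HealthState.POST_FIRST_REVISION_EARLY,
                      HealthState.POST_FIRST_REVISION_LATE):
            row = build_transition_row(state, "THA", 65, "F", 0,
                                       params, life_table)
            assert row[HealthState.POST_SECOND_REVISION] > 0.0

    @pytest.mark.parametrize("state", list(ENGINE_STATES))
    @pytest.mark.parametrize("age", [45, 74, 75, 109, 110])
    def test_every_row_sums_to_one(self, params, life_table, state, age):
        arm = "THA" if state not in ("MORE_SEVERE_OA",) else "nonoperative"
        row = engine_transition_row(state, arm, age, "F", params, life_table)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)
        assert (row >= 0).all()

    def test_conflicting_rates_raise(self, params, life_table):
        p = params.copy()
        p.second_revision_rates["early/aseptic"] = 0.9
        p.second_revision_rates["early/infection"] = 0.3
        with pytest.raises(ParameterConflictError):
            build_transition_row(HealthState.POST_FIRST_REVISION_EARLY,
                                 "THA", 60, "M", 0, p, life_table)


class TestCohort:
    def test_mass_conserved_and_dead_monotone(self, params, life_table, profile):
        for arm in ("THA", "nonoperative"):
            tr = run_cohort(arm, 60, "M", params, life_table, profile)
            sums = tr.occupancy.sum(axis=1).to_numpy()
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            dead = tr.occupancy["DEAD"].to_numpy()
            assert (np.diff(dead) >= -1e-12).all()

    def test_zero_utilities_give_zero_qaly(self, params, life_table):
        p = params.copy()
        p.utilities = {k: ({g: 0.0 for g in v} if isinstance(v, dict) else 0.0)
                       for k, v in p.utilities.items()}
        tr = run_cohort("nonoperative", 60, "M", p, life_table)
        assert tr.total_qaly == 0.0

    def test_undiscounted_qaly_closed_form_with_deterministic_death(self, params):
        p = params.copy()
        p.discount_rate = 0.0
        p.oa_progression_prob = 0.0
        lt = step_life_table(death_age=70)
        tr = run_cohort("nonoperative", 60, "M", p, lt)
        # alive for ages 60..70 inclusive: 11 cycles at the end-stage utility
        u = p.utility("end_stage_oa", "M")
        assert tr.total_qaly == pytest.approx(11 * u)

    def test_identical_arms_give_zero_incremental(self, params, life_table):
        p = equalized_arms(params)
        tha = run_cohort("THA", 60, "F", p, life_table).outcome()
        non = run_cohort("nonoperative", 60, "F", p, life_table).outcome()
        assert tha.qaly == pytest.approx(non.qaly, abs=1e-9)
        assert tha.direct_cost == pytest.approx(non.direct_cost, abs=1e-6)
        assert tha.indirect_benefit == non.indirect_benefit == 0.0

    def test_qaly_decreases_with_any_utility_decrement(self, params, life_table):
        base = run_cohort("THA", 60, "M", params, life_table).total_qaly
        for key in ("successful_tha", "post_first_revision", "initial_post_tha"):
            p = params.copy()
            v = p.utilities[key]
            if isinstance(v, dict):
                p.utilities[key] = {g: x * 0.9 for g, x in v.items()}
            else:
                p.utilities[key] = v * 0.9
            assert run_cohort("THA", 60, "M", p, life_table).total_qaly < base

    def test_cost_increases_with_any_state_cost(self, params, life_table):
        base = run_cohort("THA", 60, "M", params, life_table).total_direct_cost
        for key in params.annual_costs:
            p = params.copy()
            p.annual_costs[key] *= 1.1
            bumped = run_cohort("THA", 60, "M", p, life_table).total_direct_cost
            assert bumped >= base
            if key != "end_stage_oa":   # unoccupied in the surgical arm
                assert bumped > base

    def test_discounting_strictly_reduces_qaly(self, params, life_table):
        p0 = params.copy()
        p0.discount_rate = 0.0
        undisc = run_cohort("THA", 60, "M", p0, life_table).total_qaly
        disc = run_cohort("THA", 60, "M", params, life_table).total_qaly
        assert disc < undisc

    def test_qaly_bounded_by_life_expectancy(self, params, life_table):
        tr = run_cohort("THA", 60, "M", params, life_table)
        le = (1.0 - tr.occupancy["DEAD"]).sum()
        assert 0 <= tr.total_qaly <= le

    def test_start_age_beyond_max_rejected(self, params, life_table):
        with pytest.raises(ValueError):
            run_cohort("THA", 110, "M", params, life_table)

    def test_trace_export_shape(self, params, life_table, profile):
        tr = run_cohort("THA", 80, "F", params, life_table, profile)
        df = tr.to_frame()
        assert set(df.columns) == {"cycle", "age", "state", "occupancy",
                                   "disc_qaly", "disc_direct", "disc_indirect"}
        assert df["cycle"].max() == len(tr.occupancy) - 1


class TestMicrosim:
    def test_seed_determinism(self, params, life_table, profile):
        a, pa = run_microsim("THA", (65, "F"), 200, params, life_table,
                             profile, seed=13)
        b, pb = run_microsim("THA", (65, "F"), 200, params, life_table,
                             profile, seed=13)
        assert a == b
        pd.testing.assert_frame_equal(pa, pb)

    def test_degenerate_transitions_reproduce_cohort_exactly(self, params):
        p = params.copy()
        p.oa_progression_prob = 1.0   # deterministic progression
        lt = step_life_table(death_age=68)
        mean, per = run_microsim("nonoperative", (60, "M"), 1, p, lt, seed=3)
        coh = run_cohort("nonoperative", 60, "M", p, lt)
        assert mean.qaly == pytest.approx(coh.total_qaly)
        assert mean.direct_cost == pytest.approx(coh.total_direct_cost)

    def test_mixed_population_sampler(self, params, life_table, profile):
        def sampler(rng, n):
            ages = rng.choice([55.0, 65.0], size=n)
            genders = np.where(rng.random(n) < 0.5, "F", "M")
            return ages, genders
        mean, per = run_microsim("THA", sampler, 500, params, life_table,
                                 profile, seed=21)
        assert set(per["age"]) == {55.0, 65.0}
        assert 0 < mean.qaly < 40

    def test_zero_individuals_rejected(self, params, life_table):
        with pytest.raises(ValueError):
            run_microsim("THA", (60, "M"), 0, params, life_table)
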