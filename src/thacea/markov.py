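"""Two-arm state-transition model for hip osteoarthritis.

The model compares immediate total hip arthroplasty (THA) with nonoperative
care over the patient's remaining lifetime, one-year cycles, as either a
deterministic cohort trace or an individual-level microsimulation drawing
from the same transition rows.

Nonoperative arm: the patient stays in end-stage osteoarthritis and may
progress (irreversibly) to a more severe state.  THA arm: the surgery year
is a transitional "initial post-THA" state carrying perioperative mortality
and possible early first revision; survivors live in "successful THA" with
an annual hazard of late first revision; post-first-revision patients may
need a second revision (higher hazard in the first year after the first
revision), after which they reside permanently in a post-second-revision
state.  Revisions are split by cause (aseptic vs infection) because their
costs differ, and routing into any revision applies a perioperative
revision mortality on top of natural mortality.  Death combines natural
and surgical risk as ``1 - (1 - q_nat)(1 - q_surg)`` and is absorbing.

Each cycle accrues discounted utility (QALYs), the state's annual direct
medical cost, and - in the THA arm only - the indirect productivity benefit
for the patient's current age band, with the surgery year receiving the
reduced first-year benefit (a fraction of the steady-state gain minus the
value of recovery days).  The nonoperative arm's productivity is the
baseline against which the benefit is measured, so it accrues zero.
No half-cycle correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import HealthState, LifeTable, ParameterSet, age_band
from .productivity import ProductivityProfile, first_year_indirect_benefit


class ParameterConflictError(Exception):
    """Competing transition probabilities from a state exceed 1."""


#: Engine states: the public health states with revision-year sub-states
#: split out by cause (costs differ) and by time since revision.
ENGINE_STATES = (
    "END_STAGE_OA",
    "MORE_SEVERE_OA",
    "INITIAL_POST_THA",
    "SUCCESSFUL_THA",
    "PFR_EARLY_ASEPTIC_NEW",      # first cycle after an early first revision
    "PFR_EARLY_INFECTION_NEW",
    "PFR_EARLY_EST",              # established post-first-revision (early)
    "PFR_LATE_ASEPTIC_NEW",
    "PFR_LATE_INFECTION_NEW",
    "PFR_LATE_EST",
    "PSR_ASEPTIC_NEW",            # second-revision transitional year
    "PSR_INFECTION_NEW",
    "PSR_EST",                    # permanent post-second-revision residence
    "DEAD",
)
_IDX = {s: i for i, s in enumerate(ENGINE_STATES)}
N_STATES = len(ENGINE_STATES)

#: Map engine states to the public health-state labels.
PUBLIC_STATE = {
    "END_STAGE_OA": HealthState.END_STAGE_OA,
    "MORE_SEVERE_OA": HealthState.MORE_SEVERE_OA,
    "INITIAL_POST_THA": HealthState.INITIAL_POST_THA,
    "SUCCESSFUL_THA": HealthState.SUCCESSFUL_THA,
    "PFR_EARLY_ASEPTIC_NEW": HealthState.POST_FIRST_REVISION_EARLY,
    "PFR_EARLY_INFECTION_NEW": HealthState.POST_FIRST_REVISION_EARLY,
    "PFR_EARLY_EST": HealthState.POST_FIRST_REVISION_EARLY,
    "PFR_LATE_ASEPTIC_NEW": HealthState.POST_FIRST_REVISION_LATE,
    "PFR_LATE_INFECTION_NEW": HealthState.POST_FIRST_REVISION_LATE,
    "PFR_LATE_EST": HealthState.POST_FIRST_REVISION_LATE,
    "PSR_ASEPTIC_NEW": HealthState.POST_SECOND_REVISION,
    "PSR_INFECTION_NEW": HealthState.POST_SECOND_REVISION,
    "PSR_EST": HealthState.POST_SECOND_REVISION,
    "DEAD": HealthState.DEAD,
}


def discount_factor(t: int, r: float) -> float:
    """(1+r)^-t; cycle 0 undiscounted."""
    if r <= -1:
        raise ValueError("discount rate must exceed -1")
    if t < 0:
        raise ValueError("cycle index must be >= 0")
    return (1.0 + r) ** (-t)


def state_utility(state: str, gender: str, p: ParameterSet) -> float:
    key = {
        "END_STAGE_OA": "end_stage_oa",
        "MORE_SEVERE_OA": "more_severe_oa",
        "INITIAL_POST_THA": "initial_post_tha",
        "SUCCESSFUL_THA": "successful_tha",
        "PFR_EARLY_ASEPTIC_NEW": "post_first_revision",
        "PFR_EARLY_INFECTION_NEW": "post_first_revision",
        "PFR_EARLY_EST": "post_first_revision",
        "PFR_LATE_ASEPTIC_NEW": "post_first_revision",
        "PFR_LATE_INFECTION_NEW": "post_first_revision",
        "PFR_LATE_EST": "post_first_revision",
        "PSR_ASEPTIC_NEW": "post_second_revision",
        "PSR_INFECTION_NEW": "post_second_revision",
        "PSR_EST": "post_second_revision",
    }.get(state)
    return 0.0 if key is None else p.utility(key, gender)


def state_cost(state: str, p: ParameterSet) -> float:
    """Annual direct medical cost of an engine state (USD/year).

    Revision years carry the cause-specific revision cost; established
    post-revision years carry the successful-THA maintenance cost (no
    separate chronic post-revision cost is published).
    """
    c = p.annual_costs
    table = {
        "END_STAGE_OA": c["end_stage_oa"],
        "MORE_SEVERE_OA": c["end_stage_oa"],
        "INITIAL_POST_THA": c["initial_post_tha"],
        "SUCCESSFUL_THA": c["successful_tha"],
        "PFR_EARLY_ASEPTIC_NEW": c["first_aseptic_revision"],
        "PFR_EARLY_INFECTION_NEW": c["first_infection_revision"],
        "PFR_EARLY_EST": c["successful_tha"],
        "PFR_LATE_ASEPTIC_NEW": c["first_aseptic_revision"],
        "PFR_LATE_INFECTION_NEW": c["first_infection_revision"],
        "PFR_LATE_EST": c["successful_tha"],
        "PSR_ASEPTIC_NEW": c["first_aseptic_revision"],
        "PSR_INFECTION_NEW": c["first_infection_revision"],
        "PSR_EST": c["successful_tha"],
        "DEAD": 0.0,
    }
    return float(table[state])


def _route_revision(row: np.ndarray, src_survive: float, rates: dict[str, float],
                    dests: dict[str, str], stay: str, q_rev: float) -> None:
    """Route surviving mass into revision destinations.

    ``rates`` maps cause -> annual revision probability.  Mass routed into
    a revision additionally faces the perioperative revision mortality
    ``q_rev``, which is added to DEAD.  The remainder stays in ``stay``.
    """
    total_rate = sum(rates.values())
    if total_rate > 1.0 + 1e-12:
        raise ParameterConflictError(
            f"revision probabilities sum to {total_rate} > 1")
    for cause, rate in rates.items():
        mass = src_survive * rate
        row[_IDX[dests[cause]]] += mass * (1.0 - q_rev)
        row[_IDX["DEAD"]] += mass * q_rev
    row[_IDX[stay]] += src_survive * (1.0 - total_rate)


def engine_transition_row(
    state: str, arm: str, age: float, gender: str,
    p: ParameterSet, lt: LifeTable,
) -> np.ndarray:
    """One row of the transition matrix over the engine states; sums to 1."""
    row = np.zeros(N_STATES)
    if state == "DEAD":
        row[_IDX["DEAD"]] = 1.0
        return row
    q_nat = lt.prob_death(age, gender)
    if age >= p.max_age:
        q_nat = 1.0

    if state == "END_STAGE_OA":
        prog = p.oa_progression_prob
        row[_IDX["DEAD"]] = q_nat
        row[_IDX["MORE_SEVERE_OA"]] = (1 - q_nat) * prog
        row[_IDX["END_STAGE_OA"]] = (1 - q_nat) * (1 - prog)
        return row
    if state == "MORE_SEVERE_OA":
        row[_IDX["DEAD"]] = q_nat
        row[_IDX["MORE_SEVERE_OA"]] = 1 - q_nat
        return row

    if arm != "THA":
        raise ValueError(f"state {state} is not reachable in arm {arm!r}")
    q_rev = p.periop_revision_mortality(age)

    if state == "INITIAL_POST_THA":
        q_surg = p.periop_tha_mortality(age, gender)
        q = 1.0 - (1.0 - q_nat) * (1.0 - q_surg)
        row[_IDX["DEAD"]] = q
        rates = {c: p.first_revision_rate("early", c, age, gender)
                 for c in ("aseptic", "infection")}
        _route_revision(row, 1.0 - q, rates,
                        {"aseptic": "PFR_EARLY_ASEPTIC_NEW",
                         "infection": "PFR_EARLY_INFECTION_NEW"},
                        "SUCCESSFUL_THA", q_rev)
        return row
    if state == "SUCCESSFUL_THA":
        row[_IDX["DEAD"]] = q_nat
        rates = {c: p.first_revision_rate("late", c, age, gender)
                 for c in ("aseptic", "infection")}
        _route_revision(row, 1.0 - q_nat, rates,
                        {"aseptic": "PFR_LATE_ASEPTIC_NEW",
                         "infection": "PFR_LATE_INFECTION_NEW"},
                        "SUCCESSFUL_THA", q_rev)
        return row
    if state in ("PFR_EARLY_ASEPTIC_NEW", "PFR_EARLY_INFECTION_NEW",
                 "PFR_LATE_ASEPTIC_NEW", "PFR_LATE_INFECTION_NEW",
                 "PFR_EARLY_EST", "PFR_LATE_EST"):
        fresh = state.endswith("_NEW")
        timing = "early" if fresh else "late"  # time since the first revision
        stay = "PFR_EARLY_EST" if "EARLY" in state else "PFR_LATE_EST"
        row[_IDX["DEAD"]] = q_nat
        rates = {c: p.second_revision_rate(timing, c)
                 for c in ("aseptic", "infection")}
        _route_revision(row, 1.0 - q_nat, rates,
                        {"aseptic": "PSR_ASEPTIC_NEW",
                         "infection": "PSR_INFECTION_NEW"},
                        stay, q_rev)
        return row
    if state in ("PSR_ASEPTIC_NEW", "PSR_INFECTION_NEW", "PSR_EST"):
        row[_IDX["DEAD"]] = q_nat
        row[_IDX["PSR_EST"]] = 1 - q_nat
        return row
    raise ValueError(f"unknown state {state!r}")


def build_transition_row(
    state: HealthState, arm: str, age: float, gender: str,
    cycles_in_state: int, p: ParameterSet, lt: LifeTable,
) -> dict[HealthState, float]:
    """Transition row over the public health states.

    ``cycles_in_state`` distinguishes the revision year (0) from
    established residence in the post-revision states and selects the
    early vs late second-revision hazard.  Cause-specific sub-states are
    aggregated with the arm's aseptic/infection mix implied by the rates.
    """
    mapping = {
        HealthState.NONSURGERY: "END_STAGE_OA",
        HealthState.END_STAGE_OA: "END_STAGE_OA",
        HealthState.MORE_SEVERE_OA: "MORE_SEVERE_OA",
        HealthState.INITIAL_POST_THA: "INITIAL_POST_THA",
        HealthState.SUCCESSFUL_THA: "SUCCESSFUL_THA",
        HealthState.DEAD: "DEAD",
    }
    if state in (HealthState.POST_FIRST_REVISION_EARLY,
                 HealthState.POST_FIRST_REVISION_LATE):
        side = "EARLY" if state is HealthState.POST_FIRST_REVISION_EARLY else "LATE"
        engine = f"PFR_{side}_ASEPTIC_NEW" if cycles_in_state == 0 else f"PFR_{side}_EST"
    elif state is HealthState.POST_SECOND_REVISION:
        engine = "PSR_ASEPTIC_NEW" if cycles_in_state == 0 else "PSR_EST"
    else:
        engine = mapping[state]
    row = engine_transition_row(engine, arm, age, gender, p, lt)
    out: dict[HealthState, float] = {s: 0.0 for s in HealthState}
    for name, prob in zip(ENGINE_STATES, row):
        out[PUBLIC_STATE[name]] += float(prob)
    return out


def transition_matrix(arm: str, age: float, gender: str,
                      p: ParameterSet, lt: LifeTable) -> np.ndarray:
    M = np.empty((N_STATES, N_STATES))
    for i, s in enumerate(ENGINE_STATES):
        if arm != "THA" and s not in ("END_STAGE_OA", "MORE_SEVERE_OA", "DEAD"):
            # unreachable in the nonoperative arm; park mass in place
            M[i] = 0.0
            M[i, i] = 1.0
            continue
        M[i] = engine_transition_row(s, arm, age, gender, p, lt)
    return M


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted accumulators of one cohort run."""

    arm: str
    start_age: float
    gender: str
    occupancy: pd.DataFrame          # cycles x engine states
    ages: np.ndarray
    disc_qaly: np.ndarray            # per-cycle contributions
    disc_direct: np.ndarray
    disc_indirect: np.ndarray

    @property
    def total_qaly(self) -> float:
        return float(self.disc_qaly.sum())

    @property
    def total_direct_cost(self) -> float:
        return float(self.disc_direct.sum())

    @property
    def total_indirect_benefit(self) -> float:
        return float(self.disc_indirect.sum())

    def outcome(self) -> "ArmOutcome":
        return ArmOutcome(
            arm=self.arm, start_age=self.start_age, gender=self.gender,
            qaly=self.total_qaly, direct_cost=self.total_direct_cost,
            indirect_benefit=self.total_indirect_benefit,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: cycle, age, state, occupancy + accumulators."""
        rows = []
        cq = np.cumsum(self.disc_qaly)
        cd = np.cumsum(self.disc_direct)
        ci = np.cumsum(self.disc_indirect)
        for t in range(len(self.occupancy)):
            for s in ENGINE_STATES:
                rows.append({
                    "cycle": t, "age": self.ages[t], "state": s,
                    "occupancy": self.occupancy.iloc[t][s],
                    "disc_qaly": cq[t], "disc_direct": cd[t],
                    "disc_indirect": ci[t],
                })
        return pd.DataFrame(rows)


@dataclass
class ArmOutcome:
    arm: str
    start_age: float
    gender: str
    qaly: float
    direct_cost: float
    indirect_benefit: float


def _start_vector(arm: str) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[_IDX["INITIAL_POST_THA" if arm == "THA" else "END_STAGE_OA"]] = 1.0
    return v


def _indirect_benefit(arm: str, t: int, age: float, gender: str,
                      p: ParameterSet, profile: ProductivityProfile | None) -> float:
    if arm != "THA" or profile is None:
        return 0.0
    gain = profile.total_change(age, gender)
    if t == 0:
        return first_year_indirect_benefit(
            gain, p, profile.daily_earnings(age, gender))
    return gain


def run_cohort(
    arm: str, start_age: float, gender: str,
    p: ParameterSet, lt: LifeTable,
    profile: ProductivityProfile | None = None,
) -> CohortTrace:
    """Propagate the cohort until (almost) everyone is dead.

    Rewards accrue at the start of each cycle for the state occupied during
    that year; transitions then apply at the year's end.  Stops when DEAD
    occupancy exceeds 1 - 1e-9 or the cohort reaches the maximum age.
    """
    if start_age >= p.max_age:
        raise ValueError("start_age must be below max_age")
    if arm not in ("THA", "nonoperative"):
        raise ValueError(f"unknown arm {arm!r}")
    util = np.array([state_utility(s, gender, p) for s in ENGINE_STATES])
    cost = np.array([state_cost(s, p) for s in ENGINE_STATES])
    r = p.discount_rate

    occ = _start_vector(arm)
    rows, ages, q_c, c_c, i_c = [], [], [], [], []
    t = 0
    while True:
        age = start_age + t
        d = discount_factor(t, r)
        alive = 1.0 - occ[_IDX["DEAD"]]
        rows.append(occ.copy())
        ages.append(age)
        q_c.append(d * float(occ @ util))
        c_c.append(d * float(occ @ cost))
        i_c.append(d * alive * _indirect_benefit(arm, t, age, gender, p, profile))
        if occ[_IDX["DEAD"]] > 1.0 - 1e-9 or age >= p.max_age:
            break
        M = transition_matrix(arm, age, gender, p, lt)
        occ = occ @ M
        t += 1

    occupancy = pd.DataFrame(rows, columns=list(ENGINE_STATES))
    return CohortTrace(
        arm=arm, start_age=start_age, gender=gender,
        occupancy=occupancy, ages=np.array(ages),
        disc_qaly=np.array(q_c), disc_direct=np.array(c_c),
        disc_indirect=np.array(i_c),
    )


def run_microsim(
    arm: str,
    population,
    n_individuals: int,
    p: ParameterSet,
    lt: LifeTable,
    profile: ProductivityProfile | None = None,
    seed: int = 0,
) -> tuple[ArmOutcome, pd.DataFrame]:
    """Individual-level stochastic mirror of :func:`run_cohort`.

    ``population`` is either a fixed ``(age, gender)`` tuple or a callable
    ``(rng, n) -> (ages, genders)``.  Returns the mean outcome over
    individuals plus a per-individual outcome frame.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    if callable(population):
        ages0, genders = population(rng, n_individuals)
        ages0 = np.asarray(ages0, dtype=float)
        genders = np.asarray(genders)
    else:
        a0, g0 = population
        ages0 = np.full(n_individuals, float(a0))
        genders = np.full(n_individuals, g0)

    util = {g: np.array([state_utility(s, g, p) for s in ENGINE_STATES])
            for g in ("M", "F")}
    cost = np.array([state_cost(s, p) for s in ENGINE_STATES])
    r = p.discount_rate
    dead = _IDX["DEAD"]

    state = np.full(n_individuals, _IDX["INITIAL_POST_THA" if arm == "THA"
                                        else "END_STAGE_OA"])
    qaly = np.zeros(n_individuals)
    direct = np.zeros(n_individuals)
    indirect = np.zeros(n_individuals)

    t = 0
    groups = {}
    for a in np.unique(ages0):
        for g in np.unique(genders):
            groups[(a, g)] = (ages0 == a) & (genders == g)
    while True:
        alive = state != dead
        if not alive.any():
            break
        d = discount_factor(t, r)
        for g in ("M", "F"):
            sel = genders == g
            if sel.any():
                qaly[sel] += d * util[g][state[sel]]
        direct += d * cost[state]
        ages_t = ages0 + t
        for (a0, g), mask in groups.items():
            live = mask & alive
            if live.any():
                indirect[live] += d * _indirect_benefit(arm, t, a0 + t, g, p, profile)
        if (ages_t >= p.max_age).all():
            state[:] = dead
            break
        # transition: one cumulative-row lookup per (age, gender) group
        u = rng.random(n_individuals)
        new_state = state.copy()
        for (a0, g), mask in groups.items():
            live = mask & alive
            if not live.any():
                continue
            M = transition_matrix(arm, a0 + t, g, p, lt)
            cum = np.cumsum(M, axis=1)
            new_state[live] = (u[live, None] > cum[state[live]]).sum(axis=1)
        dying_age = ages0 + t >= p.max_age
        new_state[dying_age] = dead
        state = np.minimum(new_state, dead)
        t += 1

    per = pd.DataFrame({
        "age": ages0, "gender": genders,
        "qaly": qaly, "direct_cost": direct, "indirect_benefit": indirect,
    })
    mean = ArmOutcome(
        arm=arm, start_age=float(ages0.mean()), gender="mixed",
        qaly=float(qaly.mean()), direct_cost=float(direct.mean()),
        indirect_benefit=float(indirect.mean()),
    )
    return mean, per
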