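"""Incremental cost-effectiveness reporting.

Results follow the societal-perspective convention of the source analysis:
incremental direct cost (A), incremental indirect cost savings (B), net
societal savings C = B - A, QALYs gained D, and an "ICER" defined as C/D -
so a negative value is a net societal cost per QALY gained, and a strategy
that both saves money overall (C > 0) and gains QALYs is labelled
Dominant.  The textbook ratio (incremental direct cost per QALY) is also
emitted as a secondary column.  Currency is reported in whole 2011 USD
(half-up rounding) while full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .markov import ArmOutcome

DOMINANT = "Dominant"


def round_usd(x: float) -> int:
    """Half-up rounding to whole dollars (matching table presentation)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CEAResult:
    """One row of the incremental societal cost-effectiveness summary."""

    subgroup: str
    incremental_direct_cost: float
    incremental_indirect_savings: float
    net_societal_savings: float
    qaly_gained: float
    icer: float | None          # net savings per QALY; None when Dominant/undefined
    label: str                  # Dominant | ICER | Undefined
    icer_direct: float | None = None   # secondary: direct cost per QALY

    def __post_init__(self) -> None:
        expected = self.incremental_indirect_savings - self.incremental_direct_cost
        if abs(expected - self.net_societal_savings) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("net savings must equal indirect savings minus direct cost")


def classify(net: float, dq: float) -> str:
    """Dominance label: Dominant iff positive net savings and QALY gain."""
    if net > 0 and dq > 0:
        return DOMINANT
    if dq == 0 and net < 0:
        return "Undefined"
    return "ICER"


def incremental_results(tha: ArmOutcome, nonop: ArmOutcome,
                        subgroup: str = "pooled") -> CEAResult:
    """Incremental societal comparison of the two arms.

    Both outcomes must come from the same start age, gender and parameters.
    """
    dc = tha.direct_cost - nonop.direct_cost
    db = tha.indirect_benefit - nonop.indirect_benefit
    dq = tha.qaly - nonop.qaly
    return from_components(dc, db, dq, subgroup)


def from_components(inc_direct: float, inc_indirect: float, qaly_gained: float,
                    subgroup: str = "pooled") -> CEAResult:
    """Build a result row from already-incremental components."""
    net = inc_indirect - inc_direct
    label = classify(net, qaly_gained)
    icer = None
    if label == "ICER":
        icer = net / qaly_gained if qaly_gained != 0 else None
        if icer is None:
            label = "Undefined"
    icer_direct = inc_direct / qaly_gained if qaly_gained != 0 else None
    return CEAResult(
        subgroup=subgroup,
        incremental_direct_cost=inc_direct,
        incremental_indirect_savings=inc_indirect,
        net_societal_savings=net,
        qaly_gained=qaly_gained,
        icer=icer, label=label, icer_direct=icer_direct,
    )


def pool_subgroups(results: list[CEAResult], weights: list[float],
                   subgroup: str = "All") -> CEAResult:
    """Weighted mean of each incremental component; weights must sum to 1."""
    if len(results) != len(weights):
        raise ValueError("one weight per result required")
    total = sum(weights)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {total}")
    dc = sum(w * r.incremental_direct_cost for r, w in zip(results, weights))
    db = sum(w * r.incremental_indirect_savings for r, w in zip(results, weights))
    dq = sum(w * r.qaly_gained for r, w in zip(results, weights))
    return from_components(dc, db, dq, subgroup)


def population_savings(per_patient_net: float, volume: float) -> float:
    """Scale per-patient net societal savings to annual procedure volume."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return per_patient_net * volume


def results_table(results: list[CEAResult]) -> pd.DataFrame:
    """Presentation table with whole-dollar rounding and labels."""
    rows = []
    for r in results:
        rows.append({
            "subgroup": r.subgroup,
            "inc_direct_cost": round_usd(r.incremental_direct_cost),
            "inc_indirect_savings": round_usd(r.incremental_indirect_savings),
            "net_societal_savings": round_usd(r.net_societal_savings),
            "qaly_gained": round(r.qaly_gained, 1),
            "icer": r.label if r.icer is None else round_usd(r.icer),
            "icer_direct_per_qaly": (
                None if r.icer_direct is None else round_usd(r.icer_direct)),
        })
    return pd.DataFrame(rows)


def lifetime_report(p, lt, profile) -> list[CEAResult]:
    """Band-level incremental results plus the pooled "All" row.

    Runs both arms at each reporting band's midpoint age for each gender,
    pools genders within a band with the band's gender weights, and pools
    bands with the operated-population age weights.
    """
    from .markov import run_cohort
    from .parameters import BAND_LABELS, BAND_MIDPOINTS

    band_rows: list[CEAResult] = []
    for band in BAND_LABELS:
        mid = BAND_MIDPOINTS[band]
        per_gender = []
        for g in ("M", "F"):
            tha = run_cohort("THA", mid, g, p, lt, profile).outcome()
            non = run_cohort("nonoperative", mid, g, p, lt, profile).outcome()
            per_gender.append(incremental_results(tha, non, f"{band}/{g}"))
        w_f = p.gender_weights[band]
        band_rows.append(pool_subgroups(per_gender, [1 - w_f, w_f], band))
    weights = [p.age_band_weights[b] for b in BAND_LABELS]
    pooled = pool_subgroups(band_rows, weights, "All")
    return band_rows + [pooled]


def published_components() -> pd.DataFrame:
    """The published lifetime incremental components by age group (inputs
    for worked-example arithmetic): columns group, inc_direct,
    inc_indirect, qaly_gained."""
    root = resources.files("thacea") / "data" / "tables"
    return pd.read_csv(Path(str(root)) / "published_lifetime_components.csv")
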