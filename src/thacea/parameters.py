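"""Model parameters for the hip-arthroplasty cost-effectiveness model.

This module owns every constant the decision model consumes: per-cycle
transition probabilities, health-state utilities, annual direct medical
costs, discounting, and the behavioural assumptions used for productivity
(retirement age, recovery days, first-year benefit fraction).  Parameters
are held in a :class:`ParameterSet`, validated on construction, and can be
round-tripped through a flat YAML file with age x gender tables stored as
companion CSV files.

Age-varying quantities are keyed by the reporting age bands used throughout
the analysis (40-49, 50-59, 60-64, 65-69, 70-74, 75+).  Values the source
literature cites but does not print (perioperative primary-THA mortality by
age and gender, registry first-revision rates by band, inpatient-sample
gender weights) ship as clearly labelled fixture values of plausible
magnitude and are fully user-overridable.
"""

from __future__ import annotations

import copy
import dataclasses
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml


class ConfigurationError(Exception):
    """A required configuration field is missing or unreadable."""


class ValidationError(ValueError):
    """A parameter value is outside its admissible range."""


class FormatError(Exception):
    """An input table violates its structural contract (gaps, columns)."""


class HealthState(enum.Enum):
    """The health states of the two-arm state-transition model.

    ``DEAD`` is absorbing.  ``POST_SECOND_REVISION`` is a transitional
    state reachable only from the post-first-revision states.
    """

    NONSURGERY = "NONSURGERY"
    END_STAGE_OA = "END_STAGE_OA"
    MORE_SEVERE_OA = "MORE_SEVERE_OA"
    INITIAL_POST_THA = "INITIAL_POST_THA"
    SUCCESSFUL_THA = "SUCCESSFUL_THA"
    POST_FIRST_REVISION_EARLY = "POST_FIRST_REVISION_EARLY"
    POST_FIRST_REVISION_LATE = "POST_FIRST_REVISION_LATE"
    POST_SECOND_REVISION = "POST_SECOND_REVISION"
    DEAD = "DEAD"


#: Reporting age bands: (label, low, high-inclusive); the last band is open.
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("40-49", 40, 49),
    ("50-59", 50, 59),
    ("60-64", 60, 64),
    ("65-69", 65, 69),
    ("70-74", 70, 74),
    ("75+", 75, 200),
)

BAND_LABELS: tuple[str, ...] = tuple(b[0] for b in AGE_BANDS)

#: Representative age used when a whole band is evaluated at a single age.
BAND_MIDPOINTS: dict[str, float] = {
    "40-49": 45.0,
    "50-59": 55.0,
    "60-64": 62.5,
    "65-69": 67.5,
    "70-74": 72.5,
    "75+": 77.0,
}

GENDERS = ("M", "F")

REVISION_TIMINGS = ("early", "late")
REVISION_CAUSES = ("aseptic", "infection")


def age_band(age: float) -> str:
    """Return the reporting band containing ``age`` (clamped below 40)."""
    for label, lo, hi in AGE_BANDS:
        if age <= hi:
            return label
    return AGE_BANDS[-1][0]


@dataclass
class ParameterSet:
    """Complete constant set for the decision model.

    Scalar fields carry their base-case values as defaults.  Table fields
    (``perioperative_tha_mortality``, ``first_revision_rates``,
    ``gender_weights``, ``age_band_weights``) have no universal defaults and
    are populated by :func:`default_parameters` from the shipped fixture.

    ``provenance`` maps field names to one of ``"published"``,
    ``"fixture"``, ``"derived"`` or ``"user"`` so downstream reports can
    distinguish literature values from plausible stand-ins and user
    overrides.
    """

    discount_rate: float = 0.03
    cycle_length: float = 1.0
    max_age: int = 110
    retirement_age: int = 75
    oa_progression_prob: float = 0.041

    # probability of death attributable to surgery itself
    perioperative_revision_mortality: dict[str, float] = field(
        default_factory=lambda: {"lt75": 0.003, "ge75": 0.012}
    )
    # keyed "timing/cause": probability/year of a second revision
    second_revision_rates: dict[str, float] = field(
        default_factory=lambda: {
            "early/aseptic": 0.0583,
            "early/infection": 0.017,
            "late/aseptic": 0.022,
            "late/infection": 0.006,
        }
    )
    aseptic_to_infection_ratio_first: float = 6.69
    aseptic_to_infection_ratio_second: float = 3.4

    # utilities: scalar, or {"M": x, "F": y} when gender-specific
    utilities: dict[str, object] = field(
        default_factory=lambda: {
            "end_stage_oa": {"M": 0.52, "F": 0.47},
            "nonsurgery": {"M": 0.52, "F": 0.47},
            "more_severe_oa": 0.28,
            "initial_post_tha": 0.74,
            "successful_tha": {"M": 0.83, "F": 0.80},
            "post_first_revision": 0.64,
            # post_second_revision filled by derive_dependent_parameters
        }
    )
    post_second_revision_utility_fraction: float = 0.90
    initial_post_tha_blend: tuple[float, float] = (0.25, 0.75)

    annual_costs: dict[str, float] = field(
        default_factory=lambda: {
            "end_stage_oa": 12_815.0,
            "initial_post_tha": 38_965.0,
            # successful_tha filled by derive_dependent_parameters
            "first_aseptic_revision": 57_141.0,
            "first_infection_revision": 95_763.0,
        }
    )
    oa_cost_offset: float = 590.0

    recovery_missed_days: float = 40.0
    first_year_indirect_fraction: float = 0.50
    workdays_per_year: float = 250.0
    medicare_to_all_payer_factor: float = 1.0
    annual_tha_volume: float = 300_000.0

    # tables keyed (band, gender) resp. (timing, cause, band, gender)
    perioperative_tha_mortality: dict[tuple[str, str], float] = field(default_factory=dict)
    first_revision_rates: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    # fraction female by band; band weight over the operated population
    gender_weights: dict[str, float] = field(default_factory=dict)
    age_band_weights: dict[str, float] = field(default_factory=dict)

    provenance: dict[str, str] = field(default_factory=dict, compare=False)

    # ------------------------------------------------------------------
    def utility(self, key: str, gender: str) -> float:
        """Utility of state ``key`` for ``gender``; scalars apply to both."""
        v = self.utilities[key]
        if isinstance(v, dict):
            return float(v[gender])
        return float(v)

    def periop_tha_mortality(self, age: float, gender: str) -> float:
        return float(self.perioperative_tha_mortality[(age_band(age), gender)])

    def periop_revision_mortality(self, age: float) -> float:
        key = "ge75" if age >= 75 else "lt75"
        return float(self.perioperative_revision_mortality[key])

    def first_revision_rate(self, timing: str, cause: str, age: float, gender: str) -> float:
        return float(self.first_revision_rates[(timing, cause, age_band(age), gender)])

    def second_revision_rate(self, timing: str, cause: str) -> float:
        return float(self.second_revision_rates[f"{timing}/{cause}"])

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ----------------------------------------------------------------------
# validation

def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


def validate_parameter_set(p: ParameterSet) -> None:
    """Raise :class:`ValidationError` on any out-of-range value."""
    _check_prob("discount-adjacent oa_progression_prob", p.oa_progression_prob)
    if p.discount_rate <= -1:
        raise ValidationError("discount_rate must exceed -1")
    for k, v in p.perioperative_revision_mortality.items():
        _check_prob(f"perioperative_revision_mortality[{k}]", v)
    for k, v in p.second_revision_rates.items():
        _check_prob(f"second_revision_rates[{k}]", v)
    for k, v in p.utilities.items():
        vals = v.values() if isinstance(v, dict) else [v]
        for u in vals:
            if not (0.0 <= u <= 1.0):
                raise ValidationError(f"utility {k} must lie in [0, 1], got {u!r}")
    for k, v in p.annual_costs.items():
        if v < 0:
            raise ValidationError(f"annual cost {k} must be >= 0, got {v!r}")
    for key, v in p.perioperative_tha_mortality.items():
        _check_prob(f"perioperative_tha_mortality[{key}]", v)
    for key, v in p.first_revision_rates.items():
        _check_prob(f"first_revision_rates[{key}]", v)
    for band, v in p.gender_weights.items():
        _check_prob(f"gender_weights[{band}]", v)
    if not (0 <= p.recovery_missed_days <= p.workdays_per_year):
        raise ValidationError("recovery_missed_days must lie in [0, workdays_per_year]")
    _check_prob("first_year_indirect_fraction", p.first_year_indirect_fraction)


# ----------------------------------------------------------------------
# derivation of dependent parameters

def derive_dependent_parameters(p: ParameterSet) -> ParameterSet:
    """Fill parameters defined in terms of others; idempotent.

    Fills, when absent:

    * post-second-revision utility = post-first-revision utility x 0.90,
      rounded to 2 decimals (the published presentation precision; the
      engine uses the rounded value),
    * initial post-THA utility as the 25% pre / 75% post blend of the
      end-stage and successful-THA utilities (per gender),
    * successful-THA annual cost = end-stage cost minus the osteoarthritis
      cost offset.

    Explicitly supplied values are never overwritten.
    """
    q = p.copy()
    if "post_second_revision" not in q.utilities:
        base = q.utilities["post_first_revision"]
        frac = q.post_second_revision_utility_fraction
        if isinstance(base, dict):
            q.utilities["post_second_revision"] = {
                g: round(v * frac, 2) for g, v in base.items()
            }
        else:
            q.utilities["post_second_revision"] = round(base * frac, 2)
        q.provenance.setdefault("utilities.post_second_revision", "derived")
    if "initial_post_tha" not in q.utilities:
        w_pre, w_post = q.initial_post_tha_blend
        q.utilities["initial_post_tha"] = {
            g: round(
                w_pre * q.utility("end_stage_oa", g)
                + w_post * q.utility("successful_tha", g),
                2,
            )
            for g in GENDERS
        }
        q.provenance.setdefault("utilities.initial_post_tha", "derived")
    if "successful_tha" not in q.annual_costs:
        q.annual_costs["successful_tha"] = (
            q.annual_costs["end_stage_oa"] - q.oa_cost_offset
        )
        q.provenance.setdefault("annual_costs.successful_tha", "derived")
    validate_parameter_set(q)
    return q


def check_revision_ratio(p: ParameterSet, order: str) -> float:
    """Aseptic-to-infection rate ratio for first or second revisions.

    Uses the early rates.  For ``order="first"`` the band-level male early
    rates are used (the rates are stored by band and gender); for
    ``order="second"`` the scalar early second-revision rates.
    """
    if order == "second":
        asep = p.second_revision_rate("early", "aseptic")
        inf = p.second_revision_rate("early", "infection")
    elif order == "first":
        band = BAND_LABELS[0]
        asep = p.first_revision_rates[("early", "aseptic", band, "M")]
        inf = p.first_revision_rates[("early", "infection", band, "M")]
    else:
        raise ValueError(f"order must be 'first' or 'second', got {order!r}")
    if inf == 0:
        raise ZeroDivisionError("infection revision rate is zero; ratio undefined")
    return asep / inf


# ----------------------------------------------------------------------
# life tables

@dataclass
class LifeTable:
    """Annual death probabilities qx by integer age and gender."""

    qx: dict[str, "pd.Series"]  # gender -> Series indexed by age

    def prob_death(self, age: float, gender: str) -> float:
        a = int(age)
        series = self.qx[gender]
        if a > series.index.max():
            raise KeyError(f"life table has no age {a} for gender {gender}")
        a = max(a, int(series.index.min()))
        return float(series.loc[a])

    @property
    def max_age(self) -> int:
        return int(min(s.index.max() for s in self.qx.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, s in self.qx.items():
            for a, q in s.items():
                rows.append({"age": int(a), "gender": g, "qx": float(q)})
        return pd.DataFrame(rows).sort_values(["gender", "age"], ignore_index=True)


def life_table_from_frame(df: pd.DataFrame, max_age: int = 110) -> LifeTable:
    required = {"age", "gender", "qx"}
    if not required.issubset(df.columns):
        raise FormatError(f"life table needs columns {sorted(required)}")
    qx: dict[str, pd.Series] = {}
    for g, sub in df.groupby("gender"):
        sub = sub.sort_values("age")
        ages = sub["age"].to_numpy()
        if len(ages) and (ages[1:] - ages[:-1] != 1).any():
            raise FormatError(f"life table ages not contiguous for gender {g}")
        if ages.max() < max_age:
            raise FormatError(
                f"life table for gender {g} ends at {ages.max()}, needs {max_age}"
            )
        vals = sub["qx"].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("life-table death probability outside [0, 1]")
        s = pd.Series(vals, index=ages.astype(int))
        if s.loc[max_age] != 1.0:
            raise ValidationError(f"qx at max_age={max_age} must be 1 for gender {g}")
        qx[str(g)] = s
    return LifeTable(qx=qx)


def load_life_table(path: str | Path, max_age: int = 110) -> LifeTable:
    """Read a ``age,gender,qx`` CSV and validate its structure."""
    df = pd.read_csv(path, float_precision="round_trip")
    return life_table_from_frame(df, max_age=max_age)


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    # repr keeps the shortest exact decimal so a round trip is bit-exact
    lt.to_frame().to_csv(path, index=False,
                         float_format=lambda x: repr(float(x)))


# ----------------------------------------------------------------------
# serialization

_SCALAR_FIELDS = (
    "discount_rate", "cycle_length", "max_age", "retirement_age",
    "oa_progression_prob", "aseptic_to_infection_ratio_first",
    "aseptic_to_infection_ratio_second", "post_second_revision_utility_fraction",
    "oa_cost_offset", "recovery_missed_days", "first_year_indirect_fraction",
    "workdays_per_year", "medicare_to_all_payer_factor", "annual_tha_volume",
)


def write_parameter_set(p: ParameterSet, directory: str | Path) -> Path:
    """Write ``parameters.yaml`` plus ``tables/*.csv`` under ``directory``."""
    directory = Path(directory)
    (directory / "tables").mkdir(parents=True, exist_ok=True)
    doc: dict = {f: getattr(p, f) for f in _SCALAR_FIELDS}
    doc["initial_post_tha_blend"] = list(p.initial_post_tha_blend)
    doc["perioperative_revision_mortality"] = dict(p.perioperative_revision_mortality)
    doc["second_revision_rates"] = dict(p.second_revision_rates)
    doc["utilities"] = p.utilities
    doc["annual_costs"] = p.annual_costs
    doc["provenance"] = p.provenance
    doc["tables"] = {
        "perioperative_tha_mortality": "tables/periop_tha_mortality.csv",
        "first_revision_rates": "tables/first_revision_rates.csv",
        "gender_weights": "tables/gender_weights.csv",
        "age_band_weights": "tables/age_band_weights.csv",
    }
    pd.DataFrame(
        [{"band": b, "gender": g, "value": v} for (b, g), v in p.perioperative_tha_mortality.items()]
    ).to_csv(directory / "tables" / "periop_tha_mortality.csv", index=False)
    pd.DataFrame(
        [
            {"timing": t, "cause": c, "band": b, "gender": g, "value": v}
            for (t, c, b, g), v in p.first_revision_rates.items()
        ]
    ).to_csv(directory / "tables" / "first_revision_rates.csv", index=False)
    pd.DataFrame(
        [{"band": b, "frac_female": v} for b, v in p.gender_weights.items()]
    ).to_csv(directory / "tables" / "gender_weights.csv", index=False)
    pd.DataFrame(
        [{"band": b, "weight": v} for b, v in p.age_band_weights.items()]
    ).to_csv(directory / "tables" / "age_band_weights.csv", index=False)
    out = directory / "parameters.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return out


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load a parameter YAML (plus companion CSV tables) into a ParameterSet.

    Unspecified scalar fields take their base-case defaults; missing tables
    raise :class:`ConfigurationError`.  Every loaded value is validated.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such parameter file: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    p = ParameterSet()
    for f in _SCALAR_FIELDS:
        if f in doc:
            setattr(p, f, type(getattr(p, f))(doc[f]))
            p.provenance[f] = "user"
    if "initial_post_tha_blend" in doc:
        p.initial_post_tha_blend = tuple(float(x) for x in doc["initial_post_tha_blend"])
    for name in ("perioperative_revision_mortality", "second_revision_rates",
                 "utilities", "annual_costs"):
        if name in doc:
            setattr(p, name, doc[name])
    if "provenance" in doc:
        prov = doc["provenance"]
        prov.update(p.provenance)
        p.provenance = prov
    tables = doc.get("tables", {})
    base = path.parent

    def _table(name: str) -> pd.DataFrame:
        if name not in tables:
            raise ConfigurationError(f"parameter file missing required table: {name}")
        return pd.read_csv(base / tables[name], float_precision="round_trip")

    tm = _table("perioperative_tha_mortality")
    p.perioperative_tha_mortality = {
        (r.band, r.gender): float(r.value) for r in tm.itertuples()
    }
    fr = _table("first_revision_rates")
    p.first_revision_rates = {
        (r.timing, r.cause, r.band, r.gender): float(r.value) for r in fr.itertuples()
    }
    gw = _table("gender_weights")
    p.gender_weights = {r.band: float(r.frac_female) for r in gw.itertuples()}
    aw = _table("age_band_weights")
    p.age_band_weights = {r.band: float(r.weight) for r in aw.itertuples()}
    validate_parameter_set(p)
    return p


def default_parameters(derived: bool = True) -> ParameterSet:
    """The shipped base-case parameter set (optionally with derived fills)."""
    root = resources.files("thacea") / "data"
    p = load_parameter_set(Path(str(root)) / "default_parameters.yaml")
    return derive_dependent_parameters(p) if derived else p
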