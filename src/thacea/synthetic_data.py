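"""Synthetic survey, patient-reported-outcome and life-table generators.

No public microdata accompany the analysis, so every downstream stage is
exercised on generated inputs with known ground truth:

* ``generate_survey`` emulates a national health-interview-style sample in
  which employment and earnings depend on seven ordinal functional-limitation
  items (walk 1/4 mile, climb 10 steps, sit 2 h, stand 2 h, stoop, carry
  10 lb, push a large object; 0 = no difficulty ... 4 = unable) through a
  textbook sample-selection mechanism: a probit employment equation and a
  log-earnings equation with correlated errors, plus exclusion variables
  (other income, another worker in the household) entering only the
  employment equation.  A fraction of earnings is masked and multiply
  imputed, mimicking survey income imputation.
* ``generate_pro_sample`` emulates the paired pre/post functional-status
  questionnaire of a hip-replacement patient sample (default n=77, ages
  near 60 with SD ~10.9, baseline functional-limitations index ~54/100),
  with surgery improving each item by a configurable effect size.
* ``generate_life_table`` builds a Gompertz mortality table standing in for
  national life tables.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import LifeTable, life_table_from_frame

FUNC_ITEMS = [f"func{i}" for i in range(1, 8)]

#: Demographic / economic columns shared by the survey generator and the
#: Heckman covariate layouts.
DEMOGRAPHICS = [
    "age", "female", "race_black", "race_other", "married",
    "family_size", "educ_somecol", "educ_college",
]
EXCLUSIONS = ["other_income_flag", "other_worker_in_household"]


@dataclass
class GroundTruth:
    """True data-generating coefficients for the synthetic survey and PRO data.

    ``probit_coefs`` and ``earnings_coefs`` map covariate names (plus
    ``"const"``) to coefficients; ``rho`` is the correlation between the
    employment and log-earnings errors; ``sigma`` is the log-earnings error
    scale; ``item_effects`` is the per-item reduction in severity produced
    by surgery (points on the 0-4 scale).
    """

    probit_coefs: dict[str, float] = field(default_factory=lambda: {
        "const": 0.9,
        "age": -0.012,
        "female": -0.35,
        "race_black": -0.10,
        "race_other": -0.05,
        "married": 0.25,
        "family_size": -0.03,
        "educ_somecol": 0.15,
        "educ_college": 0.35,
        "other_income_flag": -0.40,
        "other_worker_in_household": 0.30,
        **{c: -0.12 for c in FUNC_ITEMS},
    })
    earnings_coefs: dict[str, float] = field(default_factory=lambda: {
        "const": 10.45,
        "age": 0.004,
        "female": -0.25,
        "race_black": -0.08,
        "race_other": -0.04,
        "married": 0.10,
        "family_size": 0.0,
        "educ_somecol": 0.15,
        "educ_college": 0.35,
        **{c: -0.04 for c in FUNC_ITEMS},
    })
    rho: float = 0.5
    sigma: float = 0.6
    item_effects: np.ndarray = field(default_factory=lambda: np.full(7, 1.5))
    baseline_item_mean: float = 2.16   # targets a 54/100 limitations index
    missing_earnings_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.item_effects = np.asarray(self.item_effects, dtype=float)
        if self.item_effects.shape != (7,):
            raise ValueError("item_effects must have length 7")


def _linear_index(df: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    idx = np.full(len(df), coefs.get("const", 0.0))
    for name, c in coefs.items():
        if name == "const":
            continue
        idx = idx + c * df[name].to_numpy(dtype=float)
    return idx


def _draw_demographics(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Working-age demographic mix of plausible US composition."""
    age = rng.integers(25, 75, size=n)
    female = rng.random(n) < 0.5
    race = rng.choice(3, size=n, p=[0.70, 0.15, 0.15])
    educ = rng.choice(3, size=n, p=[0.40, 0.30, 0.30])
    return pd.DataFrame({
        "age": age.astype(float),
        "female": female.astype(int),
        "race_black": (race == 1).astype(int),
        "race_other": (race == 2).astype(int),
        "married": (rng.random(n) < 0.55).astype(int),
        "family_size": rng.integers(1, 6, size=n).astype(float),
        "educ_somecol": (educ == 1).astype(int),
        "educ_college": (educ == 2).astype(int),
    })


def _draw_items(n: int, rng: np.random.Generator, age: np.ndarray,
                age_slope: float = 0.015, base: float = 0.4) -> np.ndarray:
    """Ordinal 0-4 functional items, severity loosely increasing with age."""
    latent = base + age_slope * (age - 50.0) + rng.normal(0.0, 0.6, size=n)
    items = latent[:, None] + rng.normal(0.0, 0.8, size=(n, 7))
    return np.clip(np.rint(items), 0, 4).astype(int)


def generate_survey(
    n: int,
    truth: GroundTruth | None = None,
    m_imputations: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an employment/earnings survey with a selection mechanism.

    Returns a long-format DataFrame with one copy of each record per
    imputation (column ``imputation_id`` in 1..m); earnings for records with
    observed income are identical across imputations, masked earnings are
    re-drawn per imputation from the true conditional distribution.
    ``earnings`` is defined only where ``employed == 1`` (NaN otherwise).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)

    df = _draw_demographics(n, rng)
    items = _draw_items(n, rng, df["age"].to_numpy())
    for j, col in enumerate(FUNC_ITEMS):
        df[col] = items[:, j]
    df["other_income_flag"] = (rng.random(n) < 0.30).astype(int)
    df["other_worker_in_household"] = (rng.random(n) < 0.55).astype(int)

    # correlated errors of the selection mechanism
    e_emp = rng.standard_normal(n)
    e_earn = truth.sigma * (
        truth.rho * e_emp + np.sqrt(1 - truth.rho**2) * rng.standard_normal(n)
    )
    emp_index = _linear_index(df, truth.probit_coefs)
    df["employed"] = (emp_index + e_emp > 0).astype(int)
    log_earn = _linear_index(df, truth.earnings_coefs) + e_earn
    earnings = np.where(df["employed"] == 1, np.exp(log_earn), np.nan)
    df["earnings"] = earnings

    # mask a fraction of observed earnings; impute per-imputation from truth
    observed = df["employed"].to_numpy() == 1
    masked = observed & (rng.random(n) < truth.missing_earnings_fraction)
    frames = []
    mean_log = _linear_index(df, truth.earnings_coefs)
    for m in range(1, m_imputations + 1):
        sub = df.copy()
        sub["imputation_id"] = m
        sub["earnings_imputed"] = masked.astype(int)
        if masked.any():
            draw = np.exp(mean_log[masked] + truth.sigma * rng.standard_normal(masked.sum()))
            col = sub["earnings"].to_numpy()
            col[masked] = draw
            sub["earnings"] = col
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out, truth


def generate_pro_sample(
    n: int = 77,
    truth: GroundTruth | None = None,
    seed: int = 0,
    age_mean: float = 60.0,
    age_sd: float = 10.94,
    frac_female: float = 0.5,
) -> pd.DataFrame:
    """Paired baseline/follow-up functional-status records for THA patients.

    Baseline items are binomial on {0..4} calibrated so the 0-100
    functional-limitations index averages about 54; follow-up items are the
    baseline minus a Poisson improvement with mean ``truth.item_effects``,
    floored at zero.  Columns: ``patient_id, age, gender, base_func1..7,
    fu_func1..7``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    age = np.clip(np.rint(rng.normal(age_mean, age_sd, size=n)), 40, 90)
    gender = np.where(rng.random(n) < frac_female, "F", "M")
    p_item = truth.baseline_item_mean / 4.0
    base = rng.binomial(4, p_item, size=(n, 7))
    improvement = rng.poisson(np.broadcast_to(truth.item_effects, (n, 7)))
    fu = np.maximum(base - improvement, 0)
    df = pd.DataFrame({"patient_id": np.arange(1, n + 1), "age": age, "gender": gender})
    for j in range(7):
        df[f"base_func{j + 1}"] = base[:, j]
        df[f"fu_func{j + 1}"] = fu[:, j]
    return df


def generate_life_table(
    shape: dict[str, float] | None = None,
    scale: dict[str, float] | None = None,
    max_age: int = 110,
) -> LifeTable:
    """Gompertz-mortality life table ``qx = 1 - exp(-integral of hazard)``.

    The hazard is ``h(x) = a * exp(b x)`` with gender-specific ``a``
    (``scale``) and ``b`` (``shape``); ``qx(max_age)`` is forced to 1.
    Defaults approximate a contemporary US population (life expectancy at
    60 in the low-to-mid 20s).
    """
    shape = shape or {"M": 0.085, "F": 0.088}
    scale = scale or {"M": 4.0e-5, "F": 2.2e-5}
    rows = []
    for g in ("M", "F"):
        a, b = scale[g], shape[g]
        if a <= 0 or b <= 0:
            raise ValueError("Gompertz shape and scale must be positive")
        ages = np.arange(0, max_age + 1)
        cumhaz = (a / b) * (np.exp(b * (ages + 1)) - np.exp(b * ages))
        qx = 1.0 - np.exp(-cumhaz)
        qx[-1] = 1.0
        rows.append(pd.DataFrame({"age": ages, "gender": g, "qx": qx}))
    return life_table_from_frame(pd.concat(rows, ignore_index=True), max_age=max_age)
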