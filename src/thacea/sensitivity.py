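"""Threshold, probabilistic and patient-level sensitivity analyses.

Threshold (breakeven) analysis scales one parameter by a multiplier and
bisects for the multiplier at which net societal savings cross zero; a
parameter whose sign never changes across 0.1x-10x of base is flagged
robust.  Probabilistic sensitivity analysis (PSA) propagates uncertainty
in the indirect-cost benefit through the model by Monte Carlo: each draw
samples a patient (age, gender) and a productivity multiplier - logistic
for male patients, lognormal for female patients - reruns both arms, and
records the incremental (cost, QALY) pair for the cost-effectiveness
plane.  The 95% confidence ellipse of the mean uses the sample covariance
divided by n with a chi-square(2) radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cea import incremental_results
from .markov import run_cohort
from .parameters import LifeTable, ParameterSet
from .productivity import ProductivityProfile


class NonMonotoneError(Exception):
    """Sampled net savings are not monotone over the requested bracket."""


class DegenerateEllipseError(Exception):
    """Points are collinear; the covariance is singular."""


@dataclass
class ThresholdResult:
    parameter: str
    scenario: tuple[float, str]          # (start age, gender)
    multiplier: float | None             # None when robust
    robust: bool
    bracket: tuple[float, float]
    tol: float
    net_at_threshold: float | None = None


# targets understood by apply_multiplier
def apply_multiplier(
    p: ParameterSet,
    profile: ProductivityProfile,
    target: str,
    m: float,
) -> tuple[ParameterSet, ProductivityProfile]:
    """Return copies with the target parameter scaled by ``m``.

    Supported targets: ``productivity`` (scales the whole profile),
    ``annual_costs.<key>``, ``first_revision_rates.<timing>.<cause>``
    (scaled across all bands and genders) and
    ``second_revision_rates.<timing>.<cause>``.
    """
    q = p.copy()
    prof = profile
    if target == "productivity":
        prof = profile.scaled(m)
    elif target.startswith("annual_costs."):
        key = target.split(".", 1)[1]
        if key not in q.annual_costs:
            raise KeyError(f"unknown cost parameter {key!r}")
        q.annual_costs[key] = q.annual_costs[key] * m
    elif target.startswith("first_revision_rates."):
        _, timing, cause = target.split(".")
        for k in list(q.first_revision_rates):
            if k[0] == timing and k[1] == cause:
                q.first_revision_rates[k] = min(q.first_revision_rates[k] * m, 1.0)
    elif target.startswith("second_revision_rates."):
        _, timing, cause = target.split(".")
        key = f"{timing}/{cause}"
        q.second_revision_rates[key] = min(q.second_revision_rates[key] * m, 1.0)
    else:
        raise KeyError(f"unsupported threshold target {target!r}")
    return q, prof


def net_savings(
    p: ParameterSet, lt: LifeTable, profile: ProductivityProfile,
    start_age: float, gender: str,
) -> float:
    """Net societal savings of surgery vs nonoperative care for one patient."""
    tha = run_cohort("THA", start_age, gender, p, lt, profile).outcome()
    non = run_cohort("nonoperative", start_age, gender, p, lt, profile).outcome()
    return incremental_results(tha, non).net_societal_savings


def bisect_zero(fn, lo: float, hi: float, tol: float = 1.0,
                max_iter: int = 200) -> tuple[float, float]:
    """Bisection root of a monotone ``fn`` with a sign change on [lo, hi].

    Stops when |fn| < tol or the bracket is below 1e-6; returns
    (root, fn(root)).
    """
    f_lo, f_hi = fn(lo), fn(hi)
    if f_lo == 0:
        return lo, 0.0
    if f_hi == 0:
        return hi, 0.0
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError("no sign change on the bracket")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = fn(mid)
        if abs(f_mid) < tol or (hi - lo) < 1e-6:
            return mid, f_mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return mid, f_mid


def threshold_search(
    p: ParameterSet,
    lt: LifeTable,
    profile: ProductivityProfile,
    target: str,
    scenario: tuple[float, str],
    bounds: tuple[float, float] = (0.1, 10.0),
    tol: float = 1.0,
) -> ThresholdResult:
    """Breakeven multiplier for one parameter at one patient scenario.

    Net savings are sampled at the bracket endpoints and midpoint to check
    monotonicity; absent a sign change within the bracket the parameter is
    flagged robust.
    """
    start_age, gender = scenario

    def net(m: float) -> float:
        q, prof = apply_multiplier(p, profile, target, m)
        return net_savings(q, lt, prof, start_age, gender)

    lo, hi = bounds
    f_lo, f_mid, f_hi = net(lo), net(0.5 * (lo + hi)), net(hi)
    if not (f_lo >= f_mid >= f_hi or f_lo <= f_mid <= f_hi):
        raise NonMonotoneError(
            f"net savings not monotone over [{lo}, {hi}] for {target}; "
            "narrow the bracket")
    if np.sign(f_lo) == np.sign(f_hi):
        return ThresholdResult(target, scenario, None, True, bounds, tol)
    root, f_root = bisect_zero(net, lo, hi, tol=tol)
    return ThresholdResult(target, scenario, root, False, bounds, tol,
                           net_at_threshold=f_root)


# ----------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass
class Ellipse:
    center: np.ndarray
    semi_axes: np.ndarray        # lengths of the semi-axes
    angle_deg: float             # orientation of the major axis
    shape: np.ndarray            # covariance of the mean (cov / n)
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.shape)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= stats.chi2.ppf(self.level, df=2)


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Confidence ellipse of the mean of a 2-d point cloud.

    Center = sample means; shape = sample covariance / n; squared radius =
    chi-square quantile at ``level`` with 2 df.  Raises
    :class:`DegenerateEllipseError` for (near-)collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 two-dimensional points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    scale = max(eigval.max(), 1.0)
    if eigval.min() <= 1e-12 * scale:
        raise DegenerateEllipseError("points are collinear")
    shape = cov / len(pts)
    r2 = stats.chi2.ppf(level, df=2)
    ev, evec = np.linalg.eigh(shape)
    order = np.argsort(ev)[::-1]
    ev, evec = ev[order], evec[:, order]
    angle = float(np.degrees(np.arctan2(evec[1, 0], evec[0, 0])))
    return Ellipse(center=center, semi_axes=np.sqrt(ev * r2),
                   angle_deg=angle, shape=shape, level=level)


@dataclass
class PSAResult:
    draws: pd.DataFrame                  # draw, inc_cost, inc_qaly, age, gender
    mean_inc_cost: float
    mean_inc_qaly: float
    tha_cost_mean: float
    tha_cost_ci: tuple[float, float]
    nonop_cost_mean: float
    nonop_cost_ci: tuple[float, float]
    fraction_cost_saving: float
    ellipse: Ellipse | None
    seed: int


DEFAULT_UNCERTAINTY = {
    "M": {"dist": "logistic", "loc": 1.0, "scale": 0.15},
    "F": {"dist": "lognormal", "loc": 0.0, "scale": 0.25},
}


def _draw_multiplier(spec: dict, rng: np.random.Generator) -> float:
    dist, loc, scale = spec["dist"], spec["loc"], spec["scale"]
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if dist == "logistic":
        return float(loc if scale == 0 else rng.logistic(loc, scale))
    if dist == "lognormal":
        return float(np.exp(loc) if scale == 0 else rng.lognormal(loc, scale))
    raise ValueError(f"unsupported distribution {dist!r}")


def run_psa(
    p: ParameterSet,
    lt: LifeTable,
    profile: ProductivityProfile,
    uncertainty: dict | None = None,
    population: dict | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo over indirect-cost uncertainty and patient mix.

    ``uncertainty`` maps gender to a productivity-multiplier distribution
    spec (``dist`` logistic|lognormal, ``loc``, ``scale``); ``population``
    sets the patient sampling distribution (``mean_age``, ``sd_age``,
    ``frac_female``).  Incremental cost is societal: incremental direct
    cost minus incremental indirect savings, so negative = cost saving.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    uncertainty = uncertainty or DEFAULT_UNCERTAINTY
    for g in ("M", "F"):
        if uncertainty[g]["dist"] not in ("logistic", "lognormal"):
            raise ValueError(f"invalid distribution spec for {g}")
    pop = {"mean_age": 66.0, "sd_age": 10.0, "frac_female": 0.42,
           **(population or {})}
    rng = np.random.default_rng(seed)

    rows = []
    cache: dict[tuple, tuple] = {}
    for k in range(n_draws):
        if pop["sd_age"] == 0:
            age = float(int(pop["mean_age"]))
        else:
            age = float(np.clip(np.rint(rng.normal(pop["mean_age"], pop["sd_age"])),
                                40, 95))
        gender = "F" if rng.random() < pop["frac_female"] else "M"
        mult = _draw_multiplier(uncertainty[gender], rng)
        key = (age, gender, round(mult, 10))
        if key in cache:
            tha, non = cache[key]
        else:
            prof = profile.scaled(mult)
            tha = run_cohort("THA", age, gender, p, lt, prof).outcome()
            non = run_cohort("nonoperative", age, gender, p, lt, prof).outcome()
            cache[key] = (tha, non)
        inc_cost = (tha.direct_cost - tha.indirect_benefit) - non.direct_cost
        inc_qaly = tha.qaly - non.qaly
        rows.append({
            "draw": k, "age": age, "gender": gender, "multiplier": mult,
            "inc_cost": inc_cost, "inc_qaly": inc_qaly,
            "tha_cost": tha.direct_cost - tha.indirect_benefit,
            "nonop_cost": non.direct_cost,
        })
    df = pd.DataFrame(rows)

    def _ci(col: str) -> tuple[float, float]:
        se = df[col].std(ddof=1) / np.sqrt(len(df))
        m = df[col].mean()
        return (float(m - 1.96 * se), float(m + 1.96 * se))

    pts = df[["inc_qaly", "inc_cost"]].to_numpy()
    try:
        ell = confidence_ellipse(pts, 0.95)
    except DegenerateEllipseError:
        ell = None
    return PSAResult(
        draws=df,
        mean_inc_cost=float(df["inc_cost"].mean()),
        mean_inc_qaly=float(df["inc_qaly"].mean()),
        tha_cost_mean=float(df["tha_cost"].mean()),
        tha_cost_ci=_ci("tha_cost"),
        nonop_cost_mean=float(df["nonop_cost"].mean()),
        nonop_cost_ci=_ci("nonop_cost"),
        fraction_cost_saving=float((df["inc_cost"] < 0).mean()),
        ellipse=ell,
        seed=seed,
    )
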