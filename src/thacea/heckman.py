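"""Two-step sample-selection (Heckman) estimator for employment and earnings.

Earnings are observed only for the employed, so a naive regression of
earnings on functional status is biased whenever the unobservables driving
employment and earnings are correlated.  The classic two-step correction is
used here:

1. a probit of employment on demographics, functional-limitation items and
   two exclusion variables (other income sources, another worker in the
   household) fitted on all records;
2. least squares of log earnings on demographics, functional items and the
   inverse Mills ratio ``lambda(z) = phi(z)/Phi(z)`` evaluated at the
   stage-1 index, on employed records only.

Survey income is multiply imputed, so fits can be pooled over imputations
with Rubin's rules.  The fitted model predicts employment probability,
conditional earnings, and expected annual productivity (employment
probability x earnings, net of the value of missed work days).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_data import DEMOGRAPHICS, EXCLUSIONS, FUNC_ITEMS

log = logging.getLogger(__name__)


class EstimationError(Exception):
    """The selection model could not be estimated (separation, singularity)."""


class LayoutError(Exception):
    """Covariates supplied do not match the fit's declared layout."""


@dataclass
class CovariateSpec:
    """Covariate layout of the two equations (both get an intercept).

    The exclusion variables must appear in the employment equation only;
    this is what identifies the selection correction beyond functional form.
    """

    employment: list[str]
    earnings: list[str]

    @classmethod
    def default(cls) -> "CovariateSpec":
        return cls(
            employment=DEMOGRAPHICS + FUNC_ITEMS + EXCLUSIONS,
            earnings=DEMOGRAPHICS + FUNC_ITEMS,
        )


@dataclass
class HeckmanFit:
    spec: CovariateSpec
    probit_coefficients: pd.Series
    earnings_coefficients: pd.Series     # includes the "imr" term
    probit_cov: pd.DataFrame
    earnings_cov: pd.DataFrame
    n_obs: int
    n_employed: int
    resid_var: float                     # stage-2 residual variance (log scale)
    log_earnings: bool = True
    smearing: bool = False               # add 1/2 resid_var on retransformation
    pooled: bool = False
    m: int = 1

    def to_json(self, path: str | Path) -> None:
        doc = {
            "spec": {"employment": self.spec.employment, "earnings": self.spec.earnings},
            "probit_coefficients": self.probit_coefficients.to_dict(),
            "earnings_coefficients": self.earnings_coefficients.to_dict(),
            "probit_cov": self.probit_cov.to_dict(),
            "earnings_cov": self.earnings_cov.to_dict(),
            "n_obs": self.n_obs, "n_employed": self.n_employed,
            "resid_var": self.resid_var, "log_earnings": self.log_earnings,
            "smearing": self.smearing, "pooled": self.pooled, "m": self.m,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HeckmanFit":
        doc = json.loads(Path(path).read_text())
        spec = CovariateSpec(**doc["spec"])
        names_p = ["const"] + spec.employment
        names_e = ["const"] + spec.earnings + ["imr"]
        return cls(
            spec=spec,
            probit_coefficients=pd.Series(doc["probit_coefficients"]).reindex(names_p),
            earnings_coefficients=pd.Series(doc["earnings_coefficients"]).reindex(names_e),
            probit_cov=pd.DataFrame(doc["probit_cov"]).reindex(index=names_p, columns=names_p),
            earnings_cov=pd.DataFrame(doc["earnings_cov"]).reindex(index=names_e, columns=names_e),
            n_obs=doc["n_obs"], n_employed=doc["n_employed"],
            resid_var=doc["resid_var"], log_earnings=doc["log_earnings"],
            smearing=doc["smearing"], pooled=doc["pooled"], m=doc["m"],
        )


def inverse_mills(z):
    """Inverse Mills ratio phi(z)/Phi(z), stable for large negative z."""
    z = np.asarray(z, dtype=float)
    out = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return out if out.ndim else float(out)


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    try:
        X = df[cols].to_numpy(dtype=float)
    except KeyError as exc:
        raise LayoutError(f"covariates missing from data: {exc}") from exc
    return np.column_stack([np.ones(len(df)), X])


def fit_heckman(
    records: pd.DataFrame,
    spec: CovariateSpec | None = None,
    log_earnings: bool = True,
    smearing: bool = False,
) -> HeckmanFit:
    """Fit the two-step selection model on a single (imputation) dataset.

    ``records`` must contain the layout's covariates plus ``employed`` and
    ``earnings`` (earnings defined where employed).  Raises
    :class:`EstimationError` on probit separation or a singular stage-2
    design.
    """
    spec = spec or CovariateSpec.default()
    if records["employed"].nunique() < 2:
        raise EstimationError("need both employed and non-employed records")

    X = _design(records, spec.employment)
    y = records["employed"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            probit = sm.Probit(y, X).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise EstimationError(f"probit estimation failed: {exc}") from exc
    if not np.all(np.isfinite(probit.params)):
        raise EstimationError("probit produced non-finite coefficients")

    imr = inverse_mills(X @ probit.params)
    emp = records["employed"].to_numpy() == 1
    Z = _design(records.loc[emp], spec.earnings)
    Z = np.column_stack([Z, imr[emp]])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise EstimationError("stage-2 design is singular")
    w = records.loc[emp, "earnings"].to_numpy(dtype=float)
    yw = np.log(w) if log_earnings else w
    ols = sm.OLS(yw, Z).fit()

    names_p = ["const"] + spec.employment
    names_e = ["const"] + spec.earnings + ["imr"]
    return HeckmanFit(
        spec=spec,
        probit_coefficients=pd.Series(probit.params, index=names_p),
        earnings_coefficients=pd.Series(ols.params, index=names_e),
        probit_cov=pd.DataFrame(probit.cov_params(), index=names_p, columns=names_p),
        earnings_cov=pd.DataFrame(ols.cov_params(), index=names_e, columns=names_e),
        n_obs=len(records),
        n_employed=int(emp.sum()),
        resid_var=float(ols.mse_resid),
        log_earnings=log_earnings,
        smearing=smearing,
    )


def fit_heckman_imputed(
    records: pd.DataFrame,
    spec: CovariateSpec | None = None,
    **kwargs,
) -> HeckmanFit:
    """Fit per imputation (column ``imputation_id``) and pool with Rubin's rules."""
    if "imputation_id" not in records.columns or records["imputation_id"].nunique() < 2:
        return fit_heckman(records, spec, **kwargs)
    fits = [
        fit_heckman(sub, spec, **kwargs)
        for _, sub in records.groupby("imputation_id", sort=True)
    ]
    return pool_imputations(fits)


def pool_imputations(fits: list[HeckmanFit]) -> HeckmanFit:
    """Combine per-imputation fits: mean coefficients; total variance =
    within-imputation mean + (1 + 1/m) x between-imputation variance."""
    if len(fits) < 2:
        raise ValueError("pooling needs at least 2 fits")
    ref = fits[0]
    for f in fits[1:]:
        if (f.spec.employment != ref.spec.employment
                or f.spec.earnings != ref.spec.earnings):
            raise LayoutError("imputation fits have mismatched covariate layouts")
    m = len(fits)

    def _pool(coef_attr: str, cov_attr: str) -> tuple[pd.Series, pd.DataFrame]:
        coefs = pd.concat([getattr(f, coef_attr) for f in fits], axis=1)
        mean = coefs.mean(axis=1)
        within = sum(getattr(f, cov_attr) for f in fits) / m
        dev = coefs.sub(mean, axis=0)
        between = (dev @ dev.T) / (m - 1)
        total = within + (1 + 1 / m) * between
        return mean, total

    pc, pv = _pool("probit_coefficients", "probit_cov")
    ec, ev = _pool("earnings_coefficients", "earnings_cov")
    return HeckmanFit(
        spec=ref.spec,
        probit_coefficients=pc, earnings_coefficients=ec,
        probit_cov=pv, earnings_cov=ev,
        n_obs=ref.n_obs, n_employed=ref.n_employed,
        resid_var=float(np.mean([f.resid_var for f in fits])),
        log_earnings=ref.log_earnings, smearing=ref.smearing,
        pooled=True, m=m,
    )


def _as_frame(covariates) -> pd.DataFrame:
    if isinstance(covariates, pd.DataFrame):
        return covariates
    if isinstance(covariates, pd.Series):
        return covariates.to_frame().T
    if isinstance(covariates, dict):
        return pd.DataFrame([covariates])
    raise LayoutError(f"unsupported covariate container: {type(covariates)!r}")


def predict_employment_prob(fit: HeckmanFit, covariates):
    """Probability of employment Phi(x'beta) for one profile or a frame."""
    df = _as_frame(covariates)
    X = _design(df, fit.spec.employment)
    p = stats.norm.cdf(X @ fit.probit_coefficients.to_numpy())
    return p if len(df) > 1 else float(p[0])


def predict_earnings(fit: HeckmanFit, covariates):
    """Expected earnings conditional on employment (USD/year).

    Includes the selection term: E[log w | employed] = z'gamma +
    beta_imr * lambda(x'beta); retransformed by exp (optionally with the
    half-residual-variance smearing adjustment).  With level-scale fits the
    linear prediction is floored at zero with a logged warning.
    """
    df = _as_frame(covariates)
    X = _design(df, fit.spec.employment)
    imr = inverse_mills(X @ fit.probit_coefficients.to_numpy())
    Z = np.column_stack([_design(df, fit.spec.earnings), np.atleast_1d(imr)])
    lin = Z @ fit.earnings_coefficients.to_numpy()
    if fit.log_earnings:
        if fit.smearing:
            lin = lin + 0.5 * fit.resid_var
        e = np.exp(lin)
    else:
        if (lin < 0).any():
            log.warning("negative predicted earnings floored at 0")
        e = np.maximum(lin, 0.0)
    return e if len(df) > 1 else float(e[0])


def expected_productivity(
    fit: HeckmanFit,
    covariates,
    missed_days: float = 0.0,
    workdays_per_year: float = 250.0,
):
    """Expected annual productivity in USD/year.

    P(employed) x E[earnings | employed], minus the value of missed work
    days priced at the daily earnings rate E/workdays:
    ``P*E*(1 - missed_days/workdays)``.
    """
    missed = np.asarray(missed_days, dtype=float)
    if np.any(missed < 0) or np.any(missed > workdays_per_year):
        raise ValueError("missed_days must lie in [0, workdays_per_year]")
    p = predict_employment_prob(fit, covariates)
    e = predict_earnings(fit, covariates)
    return p * e * (1.0 - missed / workdays_per_year)
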