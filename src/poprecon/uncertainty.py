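"""Standard errors, goodness-of-fit variance inflation, and derived CIs.

Standard errors come from the inverse of the numerical Hessian of half the
chi-square objective at the optimum (so that the objective behaves like a
-2 log-likelihood and a pure quadratic ``(x-a)^2/s`` yields SE ``sqrt(s)``).
Because reconstruction models tend to understate uncertainty, all variances
are then inflated by the goodness-of-fit scale parameter

    c = chi2_df / df,    df = A * Y - K,

where the chi-square statistic is computed over the observed survey cells
against their fitted expectations (telemetry terms excluded), A is the
number of classes, Y the number of years and K the number of free
parameters.  The factor multiplies variances (SE * sqrt(c)) and is floored
at 1: it guards against understated uncertainty and is never used to
shrink it.

Confidence intervals for derived quantities (annual totals, per-capita
recruitment) use the delta method through the cohort-projection recursion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tools.numdiff import approx_fprime, approx_hess3

from .io import SurveyMatrix
from .reconstruction import (
    ParameterVector,
    ReconstructedPopulation,
    build_expected,
    cell_chisq,
    per_capita_recruitment,
)

__all__ = ["UncertaintyReport", "hessian_se", "inflate", "derived_ci"]

logger = logging.getLogger(__name__)


@dataclass
class UncertaintyReport:
    """Per-parameter uncertainty at the optimum.

    ``inflation_factor`` is the raw goodness-of-fit ratio ``chi2_df / df``;
    the factor actually applied to variances is ``max(1, c)``.  Parameters
    flagged in ``flagged`` (boundary-pinned, or a non-PD Hessian direction)
    carry missing SEs.
    """

    theta: ParameterVector
    se_raw: np.ndarray
    cov_raw: np.ndarray
    flagged: np.ndarray  # bool per parameter
    df: int = 0
    k: int = 0
    inflation_factor: float = np.nan
    se_inflated: np.ndarray | None = None
    ci90: np.ndarray | None = None  # (K, 2) on the natural scale

    @property
    def applied_inflation(self) -> float:
        c = self.inflation_factor
        return 1.0 if not np.isfinite(c) else max(1.0, c)

    @property
    def cov_inflated(self) -> np.ndarray:
        return self.cov_raw * self.applied_inflation

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "quantity": self.theta.names(),
                "estimate": self.theta.flatten(),
                "se_raw": self.se_raw,
            }
        )
        if self.se_inflated is not None:
            df["se_inflated"] = self.se_inflated
        if self.ci90 is not None:
            df["ci90_low"] = self.ci90[:, 0]
            df["ci90_high"] = self.ci90[:, 1]
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def hessian_se(
    theta_hat: ParameterVector,
    objective: Callable[[np.ndarray], float],
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> UncertaintyReport:
    """Inverse-Hessian standard errors at the minimum chi-square estimate.

    The Hessian of ``objective(x) / 2`` is estimated by central finite
    differences on the natural parameter scale.  A non-positive-definite
    Hessian triggers a warning and a pseudo-inverse fallback; directions
    with non-positive curvature, and parameters pinned at a bound, are
    flagged and reported with missing SEs.
    """
    x = theta_hat.flatten()
    k = len(x)

    def half_obj(v: np.ndarray) -> float:
        return 0.5 * objective(np.asarray(v, dtype=float))

    hess = approx_hess3(x, half_obj)
    hess = 0.5 * (hess + hess.T)

    flagged = np.zeros(k, dtype=bool)
    if bounds is not None:
        lo, hi = bounds
        tol = 1e-6 * np.maximum(1.0, np.abs(x))
        flagged |= (x - lo < tol) | (hi - x < tol)

    eigvals = np.linalg.eigvalsh(hess)
    if eigvals.min() <= 0:
        warnings.warn(
            "Hessian not positive definite at the reported optimum; "
            "using pseudo-inverse and flagging affected parameters",
            RuntimeWarning,
            stacklevel=2,
        )
        cov = np.linalg.pinv(hess)
    else:
        cov = np.linalg.inv(hess)

    diag = np.diag(cov).copy()
    flagged |= diag <= 0
    se = np.full(k, np.nan)
    ok = ~flagged & (diag > 0)
    se[ok] = np.sqrt(diag[ok])
    return UncertaintyReport(
        theta=theta_hat, se_raw=se, cov_raw=cov, flagged=flagged, k=k
    )


def inflate(
    report: UncertaintyReport,
    fit: ReconstructedPopulation,
    survey: SurveyMatrix,
) -> UncertaintyReport:
    """Apply the goodness-of-fit variance inflation ``c = chi2_df / df``.

    The chi-square statistic runs over observed survey cells only; df is
    the cell count ``A * Y`` minus the number of free parameters K.
    Variances are multiplied by ``max(1, c)`` (SEs by its square root);
    a sub-unit factor is logged but never used to deflate.
    """
    A = survey.counts.shape[1]
    df = A * survey.n_years - report.k
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom: {df}")
    mask = survey.observed
    chi2 = float(np.sum(cell_chisq(survey.counts[mask], fit.abundance[mask])))
    c = chi2 / df
    if c < 1:
        logger.info("inflation factor %.3f < 1; variances left unscaled", c)
    logger.info("df = %d, chi2_df = %.2f, inflation factor = %.3f", df, chi2, c)
    se_inf = report.se_raw * np.sqrt(max(1.0, c))
    z = stats.norm.ppf(0.95)
    est = report.theta.flatten()
    ci90 = np.column_stack([est - z * se_inf, est + z * se_inf])
    # Survival parameters live in [0, 1]; abundances are non-negative.
    n_surv = report.theta.n_years - 1
    ci90[:n_surv] = np.clip(ci90[:n_surv], 0.0, 1.0)
    ci90[n_surv:] = np.maximum(ci90[n_surv:], 0.0)
    return replace(
        report, df=df, inflation_factor=c, se_inflated=se_inf, ci90=ci90
    )


def derived_ci(
    recon: ReconstructedPopulation,
    report: UncertaintyReport,
    alpha: float = 0.10,
) -> pd.DataFrame:
    """Delta-method CIs for annual totals and per-capita recruitment.

    Propagates the (inflated) parameter covariance through the Jacobian of
    the projection recursion; returns normal intervals at level
    ``1 - alpha``, floored at 0.
    """
    theta = report.theta
    years = theta.years
    Y = theta.n_years

    def derived(x: np.ndarray) -> np.ndarray:
        t = ParameterVector.from_flat(years, np.asarray(x, dtype=float))
        rec = build_expected(t)
        return np.concatenate(
            [rec.total, per_capita_recruitment(rec).to_numpy()]
        )

    x = theta.flatten()
    vals = derived(x)
    jac = approx_fprime(x, derived, centered=True)
    var = np.einsum("ij,jk,ik->i", jac, report.cov_inflated, jac)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    lo = np.maximum(vals - z * se, 0.0)
    hi = np.maximum(vals + z * se, 0.0)
    names = [f"total_{y}" for y in years] + [f"R_{y}" for y in years[:-1]]
    return pd.DataFrame(
        {
            "quantity": names,
            "year": np.concatenate([years, years[:-1]]),
            "estimate": vals,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
        }
    )
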