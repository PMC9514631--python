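"""Rate forecasting and stochastic multi-year cohort projection.

Fitted annual survival and per-capita recruitment series are forecast
beyond the data with an AR(1)-with-drift model fitted by least squares on
a transformed scale (logit for survival, log for recruitment), which keeps
every forecast inside its natural range.  The projection then propagates
the last reconstructed cohort state forward year by year, drawing each
year's survival and recruitment from its forecast distribution (parameter /
environmental stochasticity); an optional flag adds demographic noise
(binomial survival, Poisson births) for synthetic studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "RateForecast",
    "ProjectionResult",
    "forecast_rates",
    "stochastic_project",
    "growth_rate",
]

_TRANSFORMS = {
    "logit": (logit, expit),
    "log": (np.log, np.exp),
}


@dataclass
class RateForecast:
    """h-step-ahead forecasts of a demographic rate.

    ``mean`` holds the back-transformed point forecasts (the median of the
    predictive distribution); ``tmean`` and ``sd`` are the mean and SD on
    the transformed (logit/log) scale, which is where draws are normal.
    """

    years: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    scale: str
    tmean: np.ndarray

    def __post_init__(self) -> None:
        if self.scale not in _TRANSFORMS:
            raise ValueError(f"unknown scale {self.scale!r}")

    def draw(self, n_sims: int, rng: np.random.Generator) -> np.ndarray:
        """Sample ``(n_sims, horizon)`` rate paths on the natural scale."""
        z = rng.normal(
            self.tmean[None, :], self.sd[None, :], (n_sims, len(self.years))
        )
        return _TRANSFORMS[self.scale][1](z)


@dataclass
class ProjectionResult:
    """Stochastic projection output: per-simulation cohort trajectories."""

    years: np.ndarray  # anchor year + projected years, length H+1
    trajectories: np.ndarray  # (n_sims, H+1, 3)
    n_sims: int
    seed: int

    @property
    def totals(self) -> np.ndarray:
        return self.trajectories.sum(axis=2)

    @property
    def median_total(self) -> np.ndarray:
        return np.median(self.totals, axis=0)

    @property
    def ci90_total(self) -> np.ndarray:
        return np.percentile(self.totals, [5, 95], axis=0).T

    def summary(self) -> pd.DataFrame:
        rows = {"year": self.years}
        for j, cls in enumerate(("calf", "adult_female", "adult_male")):
            t = self.trajectories[:, :, j]
            rows[f"{cls}_median"] = np.median(t, axis=0)
            rows[f"{cls}_ci90_low"] = np.percentile(t, 5, axis=0)
            rows[f"{cls}_ci90_high"] = np.percentile(t, 95, axis=0)
        rows["total_median"] = self.median_total
        rows["total_ci90_low"] = self.ci90_total[:, 0]
        rows["total_ci90_high"] = self.ci90_total[:, 1]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.summary().to_csv(path, index=False)


def forecast_rates(
    series: pd.Series, horizon: int, scale: str = "logit"
) -> RateForecast:
    """Forecast a rate series ``horizon`` steps ahead.

    An AR(1) with drift, ``y_t = c + phi * y_{t-1} + e_t``, is fitted by
    ordinary least squares on the transformed scale.  Prediction SDs
    accumulate the innovation variance through the AR recursion.  When the
    fit is degenerate (constant series, or |phi| > 1), the model falls back
    to a random walk whose innovation SD is the SD of the historical
    one-step differences.

    Parameters
    ----------
    series
        Historical values indexed by calendar year; at least 5 required.
    horizon
        Number of future years to forecast.
    scale
        ``"logit"`` for probabilities, ``"log"`` for positive rates.
    """
    vals = series.dropna()
    if len(vals) < 5:
        raise ValueError("need at least 5 historical values to forecast")
    fwd, _ = _TRANSFORMS[scale]
    y = fwd(vals.to_numpy(dtype=float))
    years = np.asarray(vals.index, dtype=int)
    future = years[-1] + 1 + np.arange(horizon)

    y_lag, y_now = y[:-1], y[1:]
    degenerate = np.std(y_lag) < 1e-12
    if not degenerate:
        X = np.column_stack([np.ones_like(y_lag), y_lag])
        (c, phi), *_ = np.linalg.lstsq(X, y_now, rcond=None)
        resid = y_now - X @ (c, phi)
        dof = max(len(y_now) - 2, 1)
        sigma = float(np.sqrt(resid @ resid / dof))
        degenerate = not np.isfinite(phi) or abs(phi) > 1 + 1e-9
    if degenerate:
        # Random-walk fallback: flat forecast from the last value, variance
        # growing linearly with the historical one-step innovation variance.
        diffs = np.diff(y)
        sigma = float(np.std(diffs)) if len(diffs) else 0.0
        tmean = np.full(horizon, y[-1])
        tvar = sigma**2 * np.arange(1, horizon + 1)
    else:
        tmean = np.empty(horizon)
        tvar = np.empty(horizon)
        m, v = y[-1], 0.0
        for h in range(horizon):
            m = c + phi * m
            v = sigma**2 + phi**2 * v
            tmean[h] = m
            tvar[h] = v
    sd = np.sqrt(tvar)
    return RateForecast(
        years=future,
        mean=_TRANSFORMS[scale][1](tmean),
        sd=sd,
        scale=scale,
        tmean=tmean,
    )


def stochastic_project(
    start: np.ndarray,
    rf_surv: RateForecast,
    rf_rec: RateForecast,
    n_sims: int = 1000,
    seed: int = 0,
    start_year: int | None = None,
    demographic: bool = False,
) -> ProjectionResult:
    """Project cohort abundances forward under forecast uncertainty.

    Each simulation draws every year's adult survival and per-capita
    recruitment from the forecast distributions and applies the cohort
    recursion: next year's calves are ``R_t * females_t``; adults receive
    half the calf cohort and survive at ``S_t``.  With ``demographic=True``
    survival is binomial and births Poisson on top of the rate draws.

    ``rf_surv.years[t]`` labels the transition out of projected year ``t``;
    the result covers the anchor year plus ``horizon`` projected years.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if len(rf_surv.years) != len(rf_rec.years):
        raise ValueError("survival and recruitment forecasts must align")
    H = len(rf_surv.years)
    start = np.asarray(start, dtype=float)
    if start_year is None:
        start_year = int(rf_surv.years[0])
    rng = np.random.default_rng(seed)
    S = np.clip(rf_surv.draw(n_sims, rng), 0.0, 1.0)
    R = rf_rec.draw(n_sims, rng)

    traj = np.empty((n_sims, H + 1, 3))
    traj[:, 0, :] = start
    for t in range(H):
        calves = traj[:, t, 0]
        females = traj[:, t, 1]
        males = traj[:, t, 2]
        if demographic:
            pool_f = np.round(calves * 0.5 + females).astype(int)
            pool_m = np.round(calves * 0.5 + males).astype(int)
            next_f = rng.binomial(pool_f, S[:, t]).astype(float)
            next_m = rng.binomial(pool_m, S[:, t]).astype(float)
            next_c = rng.poisson(R[:, t] * females).astype(float)
        else:
            next_f = (calves * 0.5 + females) * S[:, t]
            next_m = (calves * 0.5 + males) * S[:, t]
            next_c = R[:, t] * females
        traj[:, t + 1, 0] = next_c
        traj[:, t + 1, 1] = next_f
        traj[:, t + 1, 2] = next_m

    years = start_year + np.arange(H + 1)
    return ProjectionResult(
        years=years, trajectories=traj, n_sims=n_sims, seed=seed
    )


def growth_rate(result: ProjectionResult) -> dict[str, float]:
    """Annual growth rate lambda over the projection horizon.

    Per trajectory, the geometric-mean yearly ratio from the anchor year to
    the final year; summarised as the median with an empirical 90% interval
    across simulations.
    """
    totals = result.totals
    if totals.shape[1] < 2:
        raise ValueError("need at least 2 projected years")
    horizon = totals.shape[1] - 1
    lam = (totals[:, -1] / totals[:, 0]) ** (1.0 / horizon)
    lo, hi = np.percentile(lam, [5, 95])
    return {
        "lambda_median": float(np.median(lam)),
        "lambda_ci90_low": float(lo),
        "lambda_ci90_high": float(hi),
    }
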