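"""Cohort projection model, chi-square objective, and minimum chi-square fit.

The population is tracked in three winter classes per year: calves, adult
females and adult males.  The free parameters are

* ``S_i`` — annual adult survival for the transition year ``i`` -> ``i+1``
  (shared by the sexes, different between years),
* ``N_11, N_12, N_13`` — initial calf / adult-female / adult-male cohort
  abundances in the first year, and
* ``N_i1`` for ``i = 2..Y`` — the calf cohort (annual recruitment) entering
  the winter population in each later year.

All adult cells follow deterministically (the invariance property): half of
last winter's calves recruit into each adult sex class and survive alongside
last winter's adults,

    N_i2 = (N_{i-1,1} * 0.5 + N_{i-1,2}) * S_{i-1}
    N_i3 = (N_{i-1,1} * 0.5 + N_{i-1,3}) * S_{i-1}

with the sex-at-birth ratio fixed at 0.5.  The fit minimises a joint
Pearson chi-square comparing (a) every observed survey cell ``a_ij`` with
its model expectation ``N_ij`` and (b) every year's observed telemetry
deaths ``v_i`` with the expected ``n_i (1 - S_i)``:

    Lambda_Joint     = sum_ij (a_ij - N_ij)^2 / N_ij
    Lambda_Telemetry = sum_i  (v_i - n_i (1 - S_i))^2 / (n_i (1 - S_i))

Minimisation is bound-constrained (survival on the logit scale, abundances
on the log scale) with multiple jittered restarts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.special import expit, logit

from .io import SurveyMatrix, TelemetryCounts, pool_telemetry

__all__ = [
    "ParameterVector",
    "ReconstructedPopulation",
    "FitConfig",
    "FitError",
    "project_adults",
    "build_expected",
    "cell_chisq",
    "joint_objective",
    "telemetry_objective",
    "make_objective",
    "fit_reconstruction",
    "per_capita_recruitment",
]

#: Floor applied to expected cell values inside the chi-square; the
#: optimisation bounds keep expectations well above it in practice.
EXPECTED_FLOOR = 1e-8


@dataclass
class ParameterVector:
    """The K = 2(Y-1) + 3 free parameters of a Y-year reconstruction."""

    years: np.ndarray  # calendar years, length Y
    survival: np.ndarray  # S_1..S_{Y-1}
    initial: np.ndarray  # N_11, N_12, N_13
    recruitment: np.ndarray  # N_21..N_Y1

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.survival = np.asarray(self.survival, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.recruitment = np.asarray(self.recruitment, dtype=float)
        Y = len(self.years)
        if len(self.survival) != Y - 1 or len(self.recruitment) != Y - 1:
            raise ValueError("survival and recruitment must have length Y-1")
        if len(self.initial) != 3:
            raise ValueError("initial must hold (N_11, N_12, N_13)")
        if not (
            np.all(np.isfinite(self.survival))
            and np.all(np.isfinite(self.initial))
            and np.all(np.isfinite(self.recruitment))
        ):
            raise ValueError("non-finite parameter")
        if np.any(self.survival < 0) or np.any(self.survival > 1):
            raise ValueError("survival outside [0, 1]")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return 2 * (self.n_years - 1) + 3

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.survival, self.initial, self.recruitment])

    @classmethod
    def from_flat(cls, years: np.ndarray, x: np.ndarray) -> "ParameterVector":
        Y = len(years)
        if len(x) != 2 * (Y - 1) + 3:
            raise ValueError("flat vector has wrong length")
        return cls(
            years=years,
            survival=x[: Y - 1],
            initial=x[Y - 1 : Y + 2],
            recruitment=x[Y + 2 :],
        )

    def names(self) -> list[str]:
        y = self.years
        return (
            [f"S_{y[i]}" for i in range(len(y) - 1)]
            + [f"N_{y[0]}_calf", f"N_{y[0]}_adult_female", f"N_{y[0]}_adult_male"]
            + [f"N_{y[i]}_calf" for i in range(1, len(y))]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names(), "estimate": self.flatten()})


@dataclass
class ReconstructedPopulation:
    """Fitted (or projected) abundance matrix ``N_ij`` and fit metadata."""

    years: np.ndarray
    abundance: np.ndarray  # (Y, 3)
    objective_value: float = np.nan
    converged: bool = True
    n_restarts_used: int = 0

    @property
    def total(self) -> np.ndarray:
        return self.abundance.sum(axis=1)

    def total_in(self, year: int) -> float:
        return float(self.total[int(np.searchsorted(self.years, year))])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.abundance, columns=["calf", "adult_female", "adult_male"]
        )
        df.insert(0, "year", self.years)
        df["total"] = self.total
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FitConfig:
    """Bounds, restart and convergence settings for the minimisation."""

    s_bounds: tuple[float, float] = (0.01, 0.999)
    n_bounds: tuple[float, float] = (1.0, 50_000.0)
    restarts: int = 10
    jitter_sd: float = 0.2
    seed: int = 0
    default_survival: float = 0.85
    gtol: float = 1e-8
    ftol: float = 1e-12
    max_iter: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FitConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if f.name.endswith("_bounds") else v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["s_bounds"] = list(self.s_bounds)
        d["n_bounds"] = list(self.n_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


class FitError(RuntimeError):
    """Raised when no restart converges; carries the best point found."""

    def __init__(self, message: str, theta: ParameterVector, objective: float):
        super().__init__(message)
        self.theta = theta
        self.objective = objective


def project_adults(
    prev_calves: float | np.ndarray,
    prev_adults: float | np.ndarray,
    s: float | np.ndarray,
) -> float | np.ndarray:
    """One step of the adult recursion: ``(calves * 0.5 + adults) * s``.

    Half of the previous winter's calf cohort recruits into the adult class
    (sex-at-birth ratio 0.5) and survives the year jointly with the previous
    adults at annual rate ``s``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("survival outside [0, 1]")
    out = (np.asarray(prev_calves, dtype=float) * 0.5 + prev_adults) * s
    return out if out.ndim else float(out)


def build_expected(theta: ParameterVector) -> ReconstructedPopulation:
    """Deterministic cohort projection of the full abundance matrix.

    Year 1 is the three initial cohorts; later calf cells are the
    recruitment parameters; later adult cells follow the invariance
    recursion exactly.
    """
    Y = theta.n_years
    N = np.empty((Y, 3))
    N[0] = theta.initial
    N[1:, 0] = theta.recruitment
    for i in range(1, Y):
        s = theta.survival[i - 1]
        N[i, 1] = (N[i - 1, 0] * 0.5 + N[i - 1, 1]) * s
        N[i, 2] = (N[i - 1, 0] * 0.5 + N[i - 1, 2]) * s
    return ReconstructedPopulation(years=theta.years.copy(), abundance=N)


def cell_chisq(observed, expected):
    """Pearson contribution ``(observed - expected)^2 / expected``.

    The expected value is floored at a tiny positive constant for numeric
    safety; a non-positive expectation after flooring is a hard error.
    """
    expected = np.maximum(np.asarray(expected, dtype=float), EXPECTED_FLOOR)
    if np.any(expected <= 0):
        raise ValueError("non-positive expected cell value")
    out = (np.asarray(observed, dtype=float) - expected) ** 2 / expected
    return out if out.ndim else float(out)


def joint_objective(theta: ParameterVector, survey: SurveyMatrix) -> float:
    """Survey part of the objective: chi-square over all observed cells.

    Year-1 and calf cells are included (each carries a free parameter that
    anchors the fit to the survey); missing cells contribute zero.
    """
    if survey.n_years != theta.n_years or survey.years[0] != theta.years[0]:
        raise ValueError("survey years do not align with parameter vector")
    N = build_expected(theta).abundance
    mask = survey.observed
    return float(np.sum(cell_chisq(survey.counts[mask], N[mask])))


def telemetry_objective(theta: ParameterVector, tc: TelemetryCounts) -> float:
    """Telemetry part: chi-square on observed vs expected annual deaths.

    For each year with telemetry, ``v_i`` is compared with the expected
    number of deaths ``n_i (1 - S_i)`` among ``n_i`` collared adults.
    Years with no telemetry contribute zero.  The upper survival bound
    keeps the denominator positive.
    """
    if not tc.pooled:
        raise ValueError("telemetry_objective requires pooled counts")
    total = 0.0
    for year, v, n in zip(tc.years, tc.deaths, tc.at_risk):
        if np.isnan(v):
            continue
        i = int(np.searchsorted(theta.years, year))
        if i >= theta.n_years or theta.years[i] != year or i > theta.n_years - 2:
            raise ValueError(
                f"telemetry year {year} has no survival parameter in the model"
            )
        exp_deaths = n * (1.0 - theta.survival[i])
        total += cell_chisq(v, exp_deaths)
    return total


def make_objective(
    survey: SurveyMatrix, tc: TelemetryCounts | None
) -> Callable[[np.ndarray], float]:
    """Composed objective on the flat natural-scale parameter vector."""

    years = survey.years

    def objective(x: np.ndarray) -> float:
        theta = ParameterVector.from_flat(years, x)
        val = joint_objective(theta, survey)
        if tc is not None:
            val += telemetry_objective(theta, tc)
        return val

    return objective


# --- optimisation transform: logit survival, log abundance ----------------


def _to_transformed(x: np.ndarray, n_surv: int) -> np.ndarray:
    z = np.empty_like(x)
    z[:n_surv] = logit(x[:n_surv])
    z[n_surv:] = np.log(x[n_surv:])
    return z


def _from_transformed(z: np.ndarray, n_surv: int) -> np.ndarray:
    x = np.empty_like(z)
    x[:n_surv] = expit(z[:n_surv])
    x[n_surv:] = np.exp(z[n_surv:])
    return x


def _initial_point(
    survey: SurveyMatrix, tc: TelemetryCounts | None, cfg: FitConfig
) -> np.ndarray:
    """Near-feasible start: telemetry survival rates and raw survey cells."""
    Y = survey.n_years
    s0 = np.full(Y - 1, cfg.default_survival)
    if tc is not None:
        for year, v, n in zip(tc.years, tc.deaths, tc.at_risk):
            if np.isnan(v):
                continue
            i = int(np.searchsorted(survey.years, year))
            if i <= Y - 2 and survey.years[i] == year:
                s0[i] = 1.0 - v / n
    s0 = np.clip(s0, cfg.s_bounds[0] + 1e-3, cfg.s_bounds[1] - 1e-3)

    counts = survey.counts.copy()
    # Missing cells: fall back to the column median so the start stays
    # interior; the objective itself ignores those cells.
    for j in range(3):
        col = counts[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmedian(col) if np.isfinite(
                np.nanmedian(col)
            ) else 100.0
    init = counts[0]
    rec = counts[1:, 0]
    n0 = np.clip(
        np.concatenate([init, rec]), cfg.n_bounds[0] * 1.01, cfg.n_bounds[1] * 0.99
    )
    return np.concatenate([s0, n0])


def fit_reconstruction(
    survey: SurveyMatrix,
    tc: TelemetryCounts | None,
    cfg: FitConfig | None = None,
) -> tuple[ParameterVector, ReconstructedPopulation]:
    """Minimum chi-square fit of the reconstruction to survey + telemetry.

    Telemetry counts are pooled (if not already) and restricted to years
    that carry a survival parameter.  The objective is minimised with
    L-BFGS-B on the transformed scale from a data-driven start plus
    ``cfg.restarts`` log-normally jittered starts (fixed seed); the best
    converged solution wins.

    Raises
    ------
    FitError
        If no start converges; the error carries the best point found.
    """
    cfg = cfg or FitConfig()
    if survey.n_years < 2:
        raise ValueError("need at least 2 survey years")
    if tc is not None and not tc.pooled:
        tc = pool_telemetry(tc, span=(survey.years[0], survey.years[-1] - 1))
    objective = make_objective(survey, tc)
    n_surv = survey.n_years - 1

    def obj_z(z: np.ndarray) -> float:
        return objective(_from_transformed(z, n_surv))

    lo = np.concatenate(
        [
            np.full(n_surv, logit(cfg.s_bounds[0])),
            np.full(n_surv + 3, np.log(cfg.n_bounds[0])),
        ]
    )
    hi = np.concatenate(
        [
            np.full(n_surv, logit(cfg.s_bounds[1])),
            np.full(n_surv + 3, np.log(cfg.n_bounds[1])),
        ]
    )
    bounds = list(zip(lo, hi))

    x0 = _initial_point(survey, tc, cfg)
    z0 = np.clip(_to_transformed(x0, n_surv), lo, hi)
    rng = np.random.default_rng(cfg.seed)
    starts = [z0]
    for _ in range(cfg.restarts):
        # Multiplicative log-normal jitter on the natural scale is additive
        # normal jitter on the transformed (log / logit-odds) scale.
        starts.append(np.clip(z0 + rng.normal(0.0, cfg.jitter_sd, len(z0)), lo, hi))

    best = None
    for z_start in starts:
        res = optimize.minimize(
            obj_z,
            z_start,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": cfg.max_iter,
                "maxfun": 20 * cfg.max_iter,
                "ftol": cfg.ftol,
                "gtol": cfg.gtol,
            },
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = ParameterVector.from_flat(
        survey.years, _from_transformed(best.x, n_surv)
    )
    recon = build_expected(theta)
    recon.objective_value = float(best.fun)
    recon.converged = bool(best.success)
    recon.n_restarts_used = cfg.restarts
    if not best.success:
        raise FitError(
            f"no restart converged: {best.message}", theta, float(best.fun)
        )
    return theta, recon


def per_capita_recruitment(recon: ReconstructedPopulation) -> pd.Series:
    """Calves next winter per adult female this winter.

    ``R_i = N_{i+1,1} / N_{i,2}`` for ``i = 1..Y-1``, indexed by the year of
    the adult-female denominator (so a 2005-2020 reconstruction yields a
    2005-2019 series).  Undefined (NaN) where the female cohort is zero.
    """
    if recon.abundance.shape[0] < 2:
        raise ValueError("need at least 2 reconstructed years")
    females = recon.abundance[:-1, 1]
    calves_next = recon.abundance[1:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(females > 0, calves_next / females, np.nan)
    return pd.Series(r, index=pd.Index(recon.years[:-1], name="year"), name="R")
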