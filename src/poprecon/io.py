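"""Reading, validation and packaging of survey and telemetry tables.

The two inputs to a reconstruction are

* an aerial-survey class-count matrix: per winter, the estimated number of
  calves, adult females and adult males in the surveyed population
  (sightability-corrected counts; class counts are derived from ratio
  estimates and therefore need not be integers), and
* telemetry mortality counts: per year, the number of collared adults that
  died (``v``) and the number at risk at the start of the year (``n``),
  possibly from several independent collaring studies.

Both are plain CSV.  The northeastern-Minnesota moose tables (winters
2005-2020 for the survey, 2005-2019 for telemetry) ship with the package and
are returned by :func:`load_survey_nemn` and :func:`load_telemetry_nemn`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "SurveyMatrix",
    "TelemetryCounts",
    "read_survey",
    "write_survey",
    "read_telemetry",
    "pool_telemetry",
    "load_survey_nemn",
    "load_telemetry_nemn",
]

#: Fixed class (column) order of the survey matrix.
CLASSES = ("calf", "adult_female", "adult_male")


@dataclass
class SurveyMatrix:
    """Observed class-by-year counts ``a_ij``.

    Parameters
    ----------
    years
        Consecutive calendar years, strictly increasing.
    counts
        Array of shape ``(Y, 3)`` with columns ``(calf, adult_female,
        adult_male)``.  A year with no survey is represented by a row of
        NaN (explicitly missing, never silently dropped).
    totals
        Optional per-year sightability-corrected totals with 90% CI bounds,
        columns ``total, ci_low, ci_high``; carried for reference only.
    """

    years: np.ndarray
    counts: np.ndarray
    totals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(CLASSES):
            raise ValueError(f"counts must be (Y, {len(CLASSES)})")
        if len(self.years) != self.counts.shape[0]:
            raise ValueError("years and counts length mismatch")
        diffs = np.diff(self.years)
        if np.any(diffs <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(diffs != 1):
            gap = int(self.years[np.argmax(diffs != 1)])
            raise ValueError(
                f"non-consecutive years: gap after {gap}; represent a skipped "
                "survey as an explicitly missing row, not by dropping the year"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.counts < 0):
                raise ValueError("negative survey count")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of cells that carry an observation."""
        return ~np.isnan(self.counts)

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in survey span")
        return idx

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(CLASSES))
        df.insert(0, "year", self.years)
        if self.totals is not None:
            df = df.merge(self.totals, on="year", how="left")
        return df


@dataclass
class TelemetryCounts:
    """Per-year collared-adult mortality counts.

    ``deaths[i]`` (``v_i``) and ``at_risk[i]`` (``n_i``) refer to calendar
    year ``years[i]``.  A year inside the span with no telemetry at all is
    kept with ``deaths = at_risk = NaN`` (an explicit "no data" marker) —
    it contributes nothing to any likelihood but is never confused with a
    zero-mortality year.  ``studies`` keeps per-record provenance; it is
    ``None`` once records have been pooled across studies.
    """

    years: np.ndarray
    deaths: np.ndarray
    at_risk: np.ndarray
    studies: list[str] | None = None
    pooled: bool = False

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=float)
        if not (len(self.years) == len(self.deaths) == len(self.at_risk)):
            raise ValueError("years/deaths/at_risk length mismatch")
        has = self.has_data
        if np.any(self.deaths[has] < 0) or np.any(self.at_risk[has] <= 0):
            raise ValueError("negative deaths or non-positive at-risk count")
        if np.any(self.deaths[has] > self.at_risk[has]):
            raise ValueError("deaths exceed at-risk")
        if np.isnan(self.deaths[has & ~np.isnan(self.at_risk)]).any():
            raise ValueError("deaths and at_risk must be missing together")

    @property
    def has_data(self) -> np.ndarray:
        return ~np.isnan(self.deaths) & ~np.isnan(self.at_risk)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"year": self.years, "deaths": self.deaths, "at_risk": self.at_risk}
        )
        if self.studies is not None:
            df.insert(1, "study", self.studies)
        return df


def read_survey(path: str | Path) -> SurveyMatrix:
    """Read an aerial-survey CSV into a validated :class:`SurveyMatrix`.

    Expected header: ``year,calf,adult_female,adult_male`` with optional
    trailing ``total,ci_low,ci_high`` columns.  Rows are normalised to
    ascending year order; blank class cells mark a missing survey year.
    """
    df = pd.read_csv(path)
    required = ["year"] + list(CLASSES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV missing columns {missing}")
    if df.empty:
        raise ValueError("no survey records")
    if df["year"].duplicated().any():
        dup = int(df.loc[df["year"].duplicated(), "year"].iloc[0])
        raise ValueError(f"duplicate year {dup}")
    df = df.sort_values("year").reset_index(drop=True)
    totals = None
    if "total" in df.columns:
        cols = [c for c in ("total", "ci_low", "ci_high") if c in df.columns]
        totals = df[["year", *cols]].copy()
    return SurveyMatrix(
        years=df["year"].to_numpy(),
        counts=df[list(CLASSES)].to_numpy(dtype=float),
        totals=totals,
    )


def write_survey(survey: SurveyMatrix, path: str | Path) -> None:
    """Write a :class:`SurveyMatrix` back to the standard CSV layout."""
    survey.to_frame().to_csv(path, index=False)


def read_telemetry(path: str | Path) -> TelemetryCounts:
    """Read per-study telemetry records (``year,study,deaths,at_risk``).

    Multiple studies may share a year; records are kept separate so that
    pooling is an explicit, order-invariant step (:func:`pool_telemetry`).
    """
    df = pd.read_csv(path)
    required = ["year", "study", "deaths", "at_risk"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry CSV missing columns {missing}")
    if (df["deaths"] < 0).any() or (df["at_risk"] <= 0).any():
        raise ValueError("negative deaths or non-positive at-risk count")
    if (df["deaths"] > df["at_risk"]).any():
        bad = df.loc[df["deaths"] > df["at_risk"]].iloc[0]
        raise ValueError(
            f"deaths exceed at-risk in {int(bad['year'])} ({bad['study']})"
        )
    return TelemetryCounts(
        years=df["year"].to_numpy(),
        deaths=df["deaths"].to_numpy(dtype=float),
        at_risk=df["at_risk"].to_numpy(dtype=float),
        studies=list(df["study"]),
        pooled=False,
    )


def pool_telemetry(
    tc: TelemetryCounts, span: tuple[int, int] | None = None
) -> TelemetryCounts:
    """Pool per-study records into one ``(v_i, n_i)`` pair per year.

    Deaths and at-risk counts are summed across studies sharing a year.
    Every year of ``span`` (default: the observed min..max year) appears in
    the result; years with no records in any study are marked "no data"
    (NaN), never silently treated as zero mortality.
    """
    lo, hi = span if span is not None else (tc.years.min(), tc.years.max())
    years = np.arange(lo, hi + 1)
    deaths = np.full(len(years), np.nan)
    at_risk = np.full(len(years), np.nan)
    for i, y in enumerate(years):
        sel = tc.years == y
        if sel.any():
            deaths[i] = tc.deaths[sel].sum()
            at_risk[i] = tc.at_risk[sel].sum()
    return TelemetryCounts(
        years=years, deaths=deaths, at_risk=at_risk, studies=None, pooled=True
    )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("poprecon").joinpath("data", name)))


def load_survey_nemn() -> SurveyMatrix:
    """Bundled northeastern-Minnesota aerial survey, winters 2005-2020."""
    return read_survey(_data_path("survey_nemn_2005_2020.csv"))


def load_telemetry_nemn() -> TelemetryCounts:
    """Bundled telemetry mortality records, four studies, 2005-2019."""
    return read_telemetry(_data_path("telemetry_nemn_2005_2019.csv"))
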