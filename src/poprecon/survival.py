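"""Annual adult survival from pooled death / at-risk counts.

The telemetry studies report, for each calendar year, the number of collared
adults at risk at the start of the year (``n``) and the number that died
(``v``).  The natural estimator on these counts is the annual survival
probability ``1 - v/n`` with binomial standard error ``sqrt(p(1-p)/n)``.
It matches Kaplan-Meier estimates exactly for years without within-year
censoring and differs only slightly otherwise.

The SE is undefined (reported as missing, not zero) in years with no
deaths or no survivors: a sample with ``v = 0`` or ``v = n`` carries no
information about the sampling variation of the rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import TelemetryCounts

__all__ = ["SurvivalSeries", "annual_survival"]


@dataclass
class SurvivalSeries:
    """Per-year survival estimates with normal-approximation CIs.

    All arrays are aligned with ``years``; entries are NaN for years marked
    "no data" (and ``se``/CI additionally when ``v`` is 0 or ``n``).
    CI bounds are clipped to [0, 1].
    """

    years: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    ci90: np.ndarray  # (Y, 2)
    ci95: np.ndarray  # (Y, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "estimate": self.estimate,
                "se": self.se,
                "ci90_low": self.ci90[:, 0],
                "ci90_high": self.ci90[:, 1],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _normal_ci(p: np.ndarray, se: np.ndarray, level: float) -> np.ndarray:
    z = stats.norm.ppf(0.5 + level / 2)
    lo = np.clip(p - z * se, 0.0, 1.0)
    hi = np.clip(p + z * se, 0.0, 1.0)
    return np.column_stack([lo, hi])


def annual_survival(tc: TelemetryCounts) -> SurvivalSeries:
    """Estimate annual survival ``1 - v/n`` from pooled telemetry counts.

    Requires pooled counts (one record per year); years marked "no data"
    propagate as missing estimates.
    """
    if not tc.pooled:
        raise ValueError("annual_survival requires pooled telemetry counts")
    with np.errstate(invalid="ignore"):
        p = 1.0 - tc.deaths / tc.at_risk
        se = np.sqrt(p * (1.0 - p) / tc.at_risk)
    # Degenerate years (v = 0 or v = n): the point estimate stands but the
    # binomial SE is uninformative -- reported missing, never 0.
    degenerate = (tc.deaths == 0) | (tc.deaths == tc.at_risk)
    se[degenerate] = np.nan
    return SurvivalSeries(
        years=tc.years.copy(),
        estimate=p,
        se=se,
        ci90=_normal_ci(p, se, 0.90),
        ci95=_normal_ci(p, se, 0.95),
    )
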