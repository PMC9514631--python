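"""Perturbation search: how much better survival or recruitment would have
been needed to avert a window of population decline.

Starting from the fitted state in the window's first year, either all
annual survival rates of the window or all recruitment cohorts entering
during the window are scaled up in 0.1% increments (linear accumulation,
``1 + 0.001 k``), the population is re-projected with the other quantity
held at its fitted value, and the search stops at the first increment for
which the end-of-window total is at least ``target_ratio`` times the
start-of-window total.  The objective is never re-minimised: the question
is about the fitted trajectory, not about refitting.  Per-year survival is
capped at 0.999.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruction import ParameterVector, ReconstructedPopulation

__all__ = ["SensitivityResult", "sensitivity_search"]

SURVIVAL_CAP = 0.999


@dataclass
class SensitivityResult:
    perturbed_quantity: str  # "survival" | "recruitment"
    percent_change: float  # steps * 0.1 (%)
    achieved_ratio: float  # N_total(end) / N_total(start)
    steps: int


def _project_window(
    state: np.ndarray,
    theta: ParameterVector,
    i0: int,
    i1: int,
    factor: float,
    quantity: str,
) -> float:
    """Total abundance at year index ``i1`` after projecting from ``state``
    at ``i0`` with the chosen quantity scaled by ``factor``."""
    calves, females, males = state
    for i in range(i0, i1):
        s = theta.survival[i]
        rec = theta.recruitment[i]  # calf cohort entering in year i+1
        if quantity == "survival":
            s = min(s * factor, SURVIVAL_CAP)
        else:
            rec = rec * factor
        females = (calves * 0.5 + females) * s
        males = (calves * 0.5 + males) * s
        calves = rec
    return calves + females + males


def sensitivity_search(
    recon: ReconstructedPopulation,
    theta_hat: ParameterVector,
    window: tuple[int, int],
    target_ratio: float = 0.9,
    quantity: str = "survival",
    max_steps: int = 50_000,
) -> SensitivityResult:
    """Smallest uniform perturbation reversing the decline over ``window``.

    Returns the first multiple of 0.1% by which the chosen quantity must be
    scaled, uniformly across the window years, for the end/start total
    ratio to reach ``target_ratio``.

    Raises
    ------
    ValueError
        If the target is unreachable (survival capped at 0.999 in every
        window year, or ``max_steps`` increments exhausted); the message
        reports the best ratio achieved.
    """
    if quantity not in ("survival", "recruitment"):
        raise ValueError(f"unknown quantity {quantity!r}")
    if not 0 < target_ratio <= 1:
        raise ValueError("target_ratio must be in (0, 1]")
    start_year, end_year = window
    years = list(theta_hat.years)
    if start_year not in years or end_year not in years:
        raise ValueError("window outside the reconstructed span")
    i0, i1 = years.index(start_year), years.index(end_year)
    if i1 <= i0:
        raise ValueError("window end must come after window start")

    start_total = float(recon.total[i0])
    state = recon.abundance[i0].copy()
    for k in range(max_steps + 1):
        factor = 1.0 + 0.001 * k
        ratio = _project_window(state, theta_hat, i0, i1, factor, quantity) / start_total
        if ratio >= target_ratio:
            return SensitivityResult(
                perturbed_quantity=quantity,
                percent_change=0.1 * k,
                achieved_ratio=ratio,
                steps=k,
            )
        if quantity == "survival" and np.all(
            theta_hat.survival[i0:i1] * factor >= SURVIVAL_CAP
        ):
            raise ValueError(
                f"target ratio {target_ratio} unreachable: survival capped at "
                f"{SURVIVAL_CAP} in every window year, best ratio {ratio:.4f}"
            )
    raise ValueError(
        f"target ratio {target_ratio} not reached within {max_steps} "
        f"increments; best ratio {ratio:.4f}"
    )
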