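"""Generate a synthetic dataset with known truth and refit it.

The decline scenario projects a known 16-year parameter vector (a herd
falling from ~8,150 to ~3,000 animals), observes it with 10% CV survey
noise and binomial telemetry mortality among 50 collars per year, and the
reconstruction is then asked to recover the truth.
"""

import numpy as np

from poprecon import (
    FitConfig,
    build_expected,
    decline_scenario,
    fit_reconstruction,
    generate,
)

truth = decline_scenario(seed=42, cv=0.10, telemetry_n=50)
survey, tc = generate(truth)
theta, recon = fit_reconstruction(survey, tc, FitConfig(restarts=1, seed=0))

true_tot = build_expected(truth.theta).total
err_s = np.abs(theta.survival - truth.theta.survival)
print(f"median |S_hat - S_true|: {np.median(err_s):.3f}")
print(
    f"true 2009->2013 decline: {1 - true_tot[8] / true_tot[4]:.1%}; "
    f"recovered: {1 - recon.total_in(2013) / recon.total_in(2009):.1%}"
)
print(
    f"total abundance error by year (|rel|, %): "
    f"{np.round(100 * np.abs(recon.total / true_tot - 1), 1)}"
)
print(
    "\nWith survey noise at 10% CV and 50 collars per year the estimator "
    "tracks annual survival to a few hundredths and yearly totals to a few "
    "percent -- the scale of error to expect on real data of this design."
)
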