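import numpy as np
import pytest

from poprecon.io import SurveyMatrix
from poprecon.reconstruction import (
    ParameterVector,
    build_expected,
    make_objective,
)
from poprecon.uncertainty import derived_ci, hessian_se, inflate


def _theta(years, survival, initial, recruitment):
    return ParameterVector(
        years=np.asarray(years),
        survival=np.asarray(survival, dtype=float),
        initial=np.asarray(initial, dtype=float),
        recruitment=np.asarray(recruitment, dtype=float),
    )


def _toy_theta():
    return _theta([1, 2, 3], [0.8, 0.7], [500.0, 900.0, 800.0], [400.0, 300.0])


def _central_diff_hessian(f, x, h=1e-5):
    """Independent second-difference Hessian used only as an oracle."""
    k = len(x)
    H = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def test_quadratic_objective_closed_form_se():
    """For 0.5 * objective = 0.5 * sum((x_k - a_k)^2 / s_k), SE_k = sqrt(s_k)."""
    theta = _toy_theta()
    a = theta.flatten()
    s = np.linspace(0.5, 4.0, len(a))

    def objective(x):
        return float(np.sum((x - a) ** 2 / s))

    rep = hessian_se(theta, objective)
    np.testing.assert_allclose(rep.se_raw, np.sqrt(s), rtol=1e-6)


def test_hessian_matches_independent_finite_differences():
    theta = _toy_theta()
    counts = build_expected(theta).abundance * np.array(
        [[1.05, 0.95, 1.0], [1.0, 1.1, 0.9], [0.97, 1.0, 1.02]]
    )
    survey = SurveyMatrix(years=[1, 2, 3], counts=counts)
    objective = make_objective(survey, None)

    rep = hessian_se(theta, objective)
    H_oracle = _central_diff_hessian(lambda x: 0.5 * objective(x), theta.flatten())
    se_oracle = np.sqrt(np.diag(np.linalg.inv(H_oracle)))
    np.testing.assert_allclose(rep.se_raw, se_oracle, rtol=1e-3)


def test_boundary_pinned_parameter_is_flagged():
    theta = _theta([1, 2], [0.999], [500.0, 900.0, 800.0], [400.0])
    a = theta.flatten()

    def objective(x):
        return float(np.sum((x - a) ** 2))

    n_surv = 1
    lo = np.array([0.01, 1, 1, 1, 1.0])
    hi = np.array([0.999, 5e4, 5e4, 5e4, 5e4])
    rep = hessian_se(theta, objective, bounds=(lo, hi))
    assert rep.flagged[0]
    assert np.isnan(rep.se_raw[0])
    assert not rep.flagged[1:].any()


def test_non_positive_definite_hessian_warns_and_falls_back():
    theta = _theta([1, 2], [0.5], [500.0, 900.0, 800.0], [400.0])
    a = theta.flatten()

    def objective(x):
        # one flat direction -> singular Hessian
        return float(np.sum((x[1:] - a[1:]) ** 2))

    with pytest.warns(RuntimeWarning, match="positive definite"):
        rep = hessian_se(theta, objective)
    assert rep.flagged[0] or np.isnan(rep.se_raw[0])
    assert np.all(np.isfinite(rep.se_raw[1:]))


def test_inflation_floor_and_df(fitted, survey, report):
    theta, recon = fitted
    # Real data: A*Y - K = 3*16 - 33
    assert report.df == 15
    assert report.k == 33
    assert report.inflation_factor > 1
    np.testing.assert_allclose(
        report.se_inflated,
        report.se_raw * np.sqrt(report.inflation_factor),
    )
    assert np.all(report.se_inflated[~report.flagged] >= report.se_raw[~report.flagged])


def test_perfect_fit_gives_zero_inflation_factor():
    theta = _toy_theta()
    recon = build_expected(theta)
    survey = SurveyMatrix(years=[1, 2, 3], counts=recon.abundance.copy())
    objective = make_objective(survey, None)
    rep = hessian_se(_toy_theta(), lambda x: float(np.sum((x - theta.flatten()) ** 2)))
    rep = inflate(rep, recon, survey)
    assert rep.inflation_factor == pytest.approx(0.0, abs=1e-12)
    # floored at 1: inflated SEs equal raw SEs
    np.testing.assert_allclose(rep.se_inflated, rep.se_raw)


def test_inflate_rejects_nonpositive_df():
    theta = _theta([1, 2], [0.8], [500.0, 900.0, 800.0], [400.0])  # K=5 > A*Y-? 6-5=1 ok
    recon = build_expected(theta)
    survey = SurveyMatrix(years=[1, 2], counts=recon.abundance.copy())
    rep = hessian_se(theta, lambda x: float(np.sum((x - theta.flatten()) ** 2)))
    rep.k = 6  # pretend one more parameter than cells allow
    with pytest.raises(ValueError, match="degrees of freedom"):
        inflate(rep, recon, survey)


def test_derived_ci_linear_map_and_zero_se():
    theta = _toy_theta()
    recon = build_expected(theta)
    survey = SurveyMatrix(years=[1, 2, 3], counts=recon.abundance * 1.03)
    objective = make_objective(survey, None)
    rep = inflate(hessian_se(theta, objective), recon, survey)

    ci = derived_ci(recon, rep, alpha=0.10)
    # Year-1 total is a linear map of (N_11, N_12, N_13): its variance is
    # the sum of the corresponding covariance block.
    n_surv = theta.n_years - 1
    block = rep.cov_inflated[n_surv : n_surv + 3, n_surv : n_surv + 3]
    se_direct = np.sqrt(block.sum())
    row = ci[ci.quantity == "total_1"].iloc[0]
    assert row.se == pytest.approx(se_direct, rel=1e-6)

    # zero covariance -> zero-width intervals
    rep0 = hessian_se(theta, lambda x: float(np.sum((x - theta.flatten()) ** 2)))
    rep0.cov_raw[:] = 0.0
    rep0 = inflate(rep0, recon, survey)
    rep0.cov_raw[:] = 0.0
    ci0 = derived_ci(recon, rep0)
    np.testing.assert_allclose(ci0.ci_low, ci0.ci_high)


def test_intervals_widen_with_confidence(fitted, report):
    theta, recon = fitted
    ci90 = derived_ci(recon, report, alpha=0.10)
    ci95 = derived_ci(recon, report, alpha=0.05)
    w90 = ci90.ci_high - ci90.ci_low
    w95 = ci95.ci_high - ci95.ci_low
    assert np.all(w95.to_numpy() >= w90.to_numpy() - 1e-9)
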