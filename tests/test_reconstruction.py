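import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poprecon.io import SurveyMatrix
from poprecon.reconstruction import (
    FitConfig,
    ParameterVector,
    build_expected,
    cell_chisq,
    fit_reconstruction,
    joint_objective,
    per_capita_recruitment,
    project_adults,
    telemetry_objective,
)
from poprecon.io import TelemetryCounts


def _theta(years, survival, initial, recruitment):
    return ParameterVector(
        years=np.asarray(years),
        survival=np.asarray(survival, dtype=float),
        initial=np.asarray(initial, dtype=float),
        recruitment=np.asarray(recruitment, dtype=float),
    )


@pytest.mark.parametrize(
    "calves, adults, s, expected",
    [(0, 100, 1.0, 100.0), (200, 300, 0.8, 320.0), (50, 0, 0.0, 0.0)],
)
def test_project_adults(calves, adults, s, expected):
    assert project_adults(calves, adults, s) == pytest.approx(expected)


def test_project_adults_rejects_bad_survival():
    with pytest.raises(ValueError):
        project_adults(1, 1, 1.5)
    with pytest.raises(ValueError):
        project_adults(1, 1, -0.1)


def test_build_expected_two_year_worked_example():
    theta = _theta([2005, 2006], [0.9], [1000, 3000, 2000], [800])
    N = build_expected(theta).abundance
    np.testing.assert_allclose(N[0], [1000, 3000, 2000])
    np.testing.assert_allclose(N[1], [800, 3150, 2250])


def test_build_expected_zero_survival_empties_adults():
    theta = _theta([1, 2, 3], [0, 0], [100, 200, 300], [50, 60])
    N = build_expected(theta).abundance
    assert np.all(N[1:, 1:] == 0)
    np.testing.assert_allclose(N[1:, 0], [50, 60])


def test_build_expected_full_survival_accumulates():
    theta = _theta([1, 2, 3, 4], [1, 1, 1], [100, 100, 100], [100, 100, 100])
    N = build_expected(theta).abundance
    assert np.all(np.diff(N[:, 1]) > 0) and np.all(np.diff(N[:, 2]) > 0)


@pytest.mark.parametrize(
    "obs, exp, value",
    [(10, 10, 0.0), (0, 4, 4.0), (3200, 3150, 0.7937)],
)
def test_cell_chisq(obs, exp, value):
    assert cell_chisq(obs, exp) == pytest.approx(value, abs=5e-5)


def test_joint_objective_perfect_fit_and_additivity():
    theta = _theta([1, 2, 3], [0.8, 0.7], [500, 900, 800], [400, 300])
    N = build_expected(theta).abundance
    survey = SurveyMatrix(years=[1, 2, 3], counts=N.copy())
    assert joint_objective(theta, survey) == pytest.approx(0.0, abs=1e-12)

    # single-cell deviation contributes exactly its cell value
    counts = N.copy()
    counts[1, 1] += 50
    survey2 = SurveyMatrix(years=[1, 2, 3], counts=counts)
    assert joint_objective(theta, survey2) == pytest.approx(
        cell_chisq(counts[1, 1], N[1, 1])
    )

    # doubling the deviation quadruples the contribution
    counts4 = N.copy()
    counts4[1, 1] += 100
    survey4 = SurveyMatrix(years=[1, 2, 3], counts=counts4)
    assert joint_objective(theta, survey4) == pytest.approx(
        4 * joint_objective(theta, survey2)
    )


def test_joint_objective_ignores_missing_cells():
    theta = _theta([1, 2, 3], [0.8, 0.7], [500, 900, 800], [400, 300])
    N = build_expected(theta).abundance
    counts = N.copy()
    counts[1, :] = np.nan  # no survey that winter
    counts[2, 0] += 30
    survey = SurveyMatrix(years=[1, 2, 3], counts=counts)
    assert joint_objective(theta, survey) == pytest.approx(
        cell_chisq(counts[2, 0], N[2, 0])
    )


def test_joint_objective_dimension_mismatch():
    theta = _theta([1, 2], [0.8], [500, 900, 800], [400])
    survey = SurveyMatrix(years=[1, 2, 3], counts=np.ones((3, 3)))
    with pytest.raises(ValueError, match="align"):
        joint_objective(theta, survey)


@given(c=st.floats(min_value=0.01, max_value=100))
@settings(max_examples=25, deadline=None)
def test_joint_objective_scale_equivariance(c):
    theta = _theta([1, 2, 3], [0.8, 0.7], [500, 900, 800], [400, 300])
    counts = build_expected(theta).abundance * np.array(
        [[1.1, 0.9, 1.0], [1.0, 1.2, 0.8], [0.95, 1.0, 1.05]]
    )
    survey = SurveyMatrix(years=[1, 2, 3], counts=counts)
    scaled_theta = _theta(
        [1, 2, 3],
        theta.survival,
        theta.initial * c,
        theta.recruitment * c,
    )
    scaled_survey = SurveyMatrix(years=[1, 2, 3], counts=counts * c)
    assert joint_objective(scaled_theta, scaled_survey) == pytest.approx(
        c * joint_objective(theta, survey), rel=1e-9
    )


@pytest.mark.parametrize(
    "v, s, value",
    [(2, 0.8, 0.0), (3, 0.8, 0.5), (9, 1 - 9 / 22, 0.0)],
)
def test_telemetry_objective(v, s, value):
    n = 10 if s == 0.8 else 22
    theta = _theta([1, 2], [s], [100, 100, 100], [50])
    tc = TelemetryCounts(
        years=np.array([1]),
        deaths=np.array([float(v)]),
        at_risk=np.array([float(n)]),
        pooled=True,
    )
    assert telemetry_objective(theta, tc) == pytest.approx(value, abs=1e-12)


def test_telemetry_objective_skips_no_data_years():
    theta = _theta([1, 2, 3], [0.8, 0.9], [100, 100, 100], [50, 50])
    tc = TelemetryCounts(
        years=np.array([1, 2]),
        deaths=np.array([2.0, np.nan]),
        at_risk=np.array([10.0, np.nan]),
        pooled=True,
    )
    assert telemetry_objective(theta, tc) == pytest.approx(0.0)


def test_parameter_vector_dimensions(fitted):
    theta, _ = fitted
    assert theta.n_years == 16
    assert theta.k == 33
    assert len(theta.flatten()) == 33
    back = ParameterVector.from_flat(theta.years, theta.flatten())
    np.testing.assert_allclose(back.survival, theta.survival)


def test_fitted_cells_satisfy_invariance_exactly(fitted):
    """Adult cells are functions of the parameters, never free-fitted."""
    theta, recon = fitted
    N = recon.abundance
    for i in range(1, theta.n_years):
        s = theta.survival[i - 1]
        assert N[i, 1] == (N[i - 1, 0] * 0.5 + N[i - 1, 1]) * s
        assert N[i, 2] == (N[i - 1, 0] * 0.5 + N[i - 1, 2]) * s
    np.testing.assert_allclose(recon.total, N.sum(axis=1))


def test_perfect_fit_recovery_small_instance():
    """A noise-free survey generated from a known truth is recovered with
    essentially zero objective."""
    years = np.arange(2000, 2006)
    theta_true = _theta(
        years,
        [0.85, 0.8, 0.75, 0.8, 0.85],
        [800, 2000, 1900],
        [700, 650, 500, 550, 600],
    )
    survey = SurveyMatrix(
        years=years, counts=build_expected(theta_true).abundance
    )
    theta_hat, recon = fit_reconstruction(
        survey, None, FitConfig(restarts=2, seed=3)
    )
    assert recon.objective_value < 1e-6
    np.testing.assert_allclose(theta_hat.survival, theta_true.survival, atol=5e-3)


def test_per_capita_recruitment_definition():
    theta = _theta([1, 2, 3], [0.8, 0.7], [500, 900, 800], [400, 0])
    recon = build_expected(theta)
    r = per_capita_recruitment(recon)
    N = recon.abundance
    assert r[1] == pytest.approx(N[1, 0] / N[0, 1])
    assert r[2] == 0.0  # no calves next winter

    # zero adult females -> undefined
    theta0 = _theta([1, 2], [0.0], [500, 0, 800], [400])
    recon0 = build_expected(theta0)
    assert np.isnan(per_capita_recruitment(recon0)[1]) or per_capita_recruitment(
        recon0
    ).isna()[1]


def test_fit_config_yaml_round_trip(tmp_path):
    cfg = FitConfig(restarts=3, seed=11, s_bounds=(0.05, 0.99))
    path = tmp_path / "fit.yaml"
    cfg.to_yaml(path)
    back = FitConfig.from_yaml(path)
    assert back == cfg
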