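import numpy as np
import pytest

from poprecon import (
    FitConfig,
    fit_reconstruction,
    hessian_se,
    inflate,
    load_survey_nemn,
    load_telemetry_nemn,
    make_objective,
    pool_telemetry,
)


@pytest.fixture(scope="session")
def survey():
    return load_survey_nemn()


@pytest.fixture(scope="session")
def telemetry_raw():
    return load_telemetry_nemn()


@pytest.fixture(scope="session")
def pooled(survey, telemetry_raw):
    return pool_telemetry(
        telemetry_raw, span=(int(survey.years[0]), int(survey.years[-1]) - 1)
    )


@pytest.fixture(scope="session")
def fitted(survey, pooled):
    """The full minimum chi-square fit to the bundled tables."""
    theta, recon = fit_reconstruction(survey, pooled, FitConfig())
    return theta, recon


@pytest.fixture(scope="session")
def report(survey, pooled, fitted):
    theta, recon = fitted
    rep = hessian_se(theta, make_objective(survey, pooled))
    return inflate(rep, recon, survey)
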