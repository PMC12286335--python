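import numpy as np
import pytest

from geoscreen import CoefficientSurface, SyntheticCohortSpec, simulate_cohort
from geoscreen.synthetic import CovariateSpec


@pytest.fixture(scope="session")
def two_cluster_cohort():
    """n=2,000 cohort with a step coefficient surface: true OR 2 in cluster A,
    4 in cluster B, clusters 200 units apart."""
    spec = SyntheticCohortSpec(
        n_participants=2000,
        surfaces=[
            CoefficientSurface.constant("intercept", -1.4),
            CoefficientSurface.two_cluster_step(
                "x1", np.log(2.0), np.log(4.0), (0.0, 0.0), (200.0, 0.0)
            ),
        ],
        covariate_specs=[CovariateSpec("x1", ("normal", 0.0, 1.0))],
        n_centres=2,
        centres=np.array([[0.0, 0.0], [200.0, 0.0]]),
        centre_spread=15.0,
        oa_group_size=5,
        seed=42,
    )
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_spatial_cohort():
    """n=300 cohort with a smooth gaussian-bump coefficient surface."""
    spec = SyntheticCohortSpec(
        n_participants=300,
        surfaces=[
            CoefficientSurface.constant("intercept", -1.2),
            CoefficientSurface.gaussian_bump("x1", np.log(3.0), (500.0, 500.0), 150.0),
        ],
        covariate_specs=[CovariateSpec("x1", ("normal", 0.0, 1.0))],
        n_centres=4,
        centre_spread=60.0,
        seed=11,
    )
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def flat_cohort_500():
    """n=500 cohort with constant surfaces, for flat-kernel oracle checks."""
    spec = SyntheticCohortSpec(
        n_participants=500,
        surfaces=[
            CoefficientSurface.constant("intercept", -1.0),
            CoefficientSurface.constant("x1", 0.7),
            CoefficientSurface.constant("x2", -0.4),
        ],
        covariate_specs=[
            CovariateSpec("x1", ("normal", 0.0, 1.0)),
            CovariateSpec("x2", ("bernoulli", 0.4)),
        ],
        n_centres=3,
        seed=7,
    )
    return spec, simulate_cohort(spec)
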