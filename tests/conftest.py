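import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from bvocflux.registry import default_registry

    return default_registry()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Clean-air, noise-free fixture covering the pre-fumigation window."""
    from bvocflux.datasets import make_study_dataset

    return make_study_dataset(
        seed=7, n_plants=2, fumigation=False, noise=False, root=True,
        t_end=10800.0,
    )


@pytest.fixture(scope="session")
def fumigation_dataset():
    """Noise-free fumigation fixture with chamber chemistry, one plant."""
    from bvocflux.datasets import make_study_dataset

    return make_study_dataset(
        seed=11, n_plants=1, fumigation=True, noise=False, root=False,
        plant_cv=0.0,
    )
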