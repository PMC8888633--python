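import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic noisy phantom case on a reduced grid."""
    from cdis.phantom import PhantomSpec, LesionSpec, TissueParams, DEFAULT_TISSUES

    spec = PhantomSpec(
        shape=(48, 48, 8),
        spacing=(2.0, 2.0, 3.0),
        gland_semiaxes_mm=(22.0, 18.0, 10.0),
        tz_semiaxes_mm=(12.0, 10.0, 6.0),
        lesions=(
            LesionSpec((10.0, 6.0, 0.0), 6.0, "csPCa", DEFAULT_TISSUES["csPCa"]),
            LesionSpec((-10.0, -4.0, 0.0), 5.0, "insPCa", DEFAULT_TISSUES["insPCa"]),
        ),
        noise_sigma=15.0,
        seed=42,
    )
    from cdis.phantom import generate_phantom

    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Six deterministic noisy phantom cases at the default geometry."""
    from cdis.phantom import default_study_spec, generate_phantom

    return [generate_phantom(s) for s in default_study_spec(6, seed=11)]
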