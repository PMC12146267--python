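import pytest
from hypothesis import HealthCheck, settings

from denikin import scenarios
from denikin.model_core import CommunityModel, SpeciesModel, SubstrateKinetics

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    return scenarios.default_parameters()


@pytest.fixture(scope="session")
def single_species_model():
    """One species, one substrate, K_s ~ 0, no inhibition.

    With the carrying capacity binding before substrate exhaustion the
    trajectory is an exact logistic, giving a closed-form oracle.
    """
    sk = SubstrateKinetics(substrate="NO3", mu_max=0.2, K_s=0.0)
    sp = SpeciesModel(
        name="solo", kinetics={"NO3": sk}, capacity_coeffs={"NO3": 0.03}
    )
    return CommunityModel(species=[sp])
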