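import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sphere_pair():
    """Small rendered sphere pair with known rotation, shared across tests."""
    from spinfit.synthetic import SyntheticConfig, render_sequence

    cfg = SyntheticConfig(
        model_type="sphere", A=140.0, B=140.0, image_size=(310, 310),
        n_views=2, rotation_deg=(20.0, 0.0), seed=2024,
    )
    return render_sequence(cfg)


@pytest.fixture(scope="session")
def sphere_pair_results(sphere_pair):
    from spinfit.model import SpheroidRotationModel

    return SpheroidRotationModel.from_synthetic(sphere_pair).fit()
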