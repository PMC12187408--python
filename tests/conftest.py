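import math

import pytest

from burstkit import FeedbackParams, NoiseScales, ToggleParams


@pytest.fixture(scope="session")
def npc_params() -> FeedbackParams:
    """Reference rate set for the neural-progenitor ultradian oscillator."""
    return FeedbackParams(
        alpha_M=39.93,
        alpha_P=21.56,
        mu_M=math.log(2) / 30.0,
        mu_P=math.log(2) / 90.0,
        h=4.78,
        P0=24201.01,
        tau=33.0,
    )


@pytest.fixture(scope="session")
def toggle_params() -> ToggleParams:
    """Bistable toggle-switch rates (high state near 9 cu, low near 1 cu)."""
    return ToggleParams(
        alpha=1.0, mu=0.1, h=2.0, P0=3.0,
        noise=NoiseScales(omega=100.0, lam=100.0),
    )


@pytest.fixture(scope="session")
def fig3_noise() -> NoiseScales:
    """Large-system, fast-bursting regime where all tiers agree."""
    return NoiseScales(omega=100.0, lam=10.0)
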