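import numpy as np
import pytest

from ecogames import DecayingResource, EcoEvoSystem, IncentiveParams, RenewingResource


@pytest.fixture
def cycling_incentives():
    """Positive-leading-incentive game in the cycle-capable region:
    deltaL1=2, deltaH1=1, dL0=3, dH0=1 (decaying-resource phase-plane
    example with a unique coexistence point at x = 1/sqrt(3))."""
    return IncentiveParams(deltaL1=2.0, deltaH1=1.0, dL0=3.0, dH0=1.0)


@pytest.fixture
def mixed_incentives():
    """Mixed-leading-incentive game with two interior equilibria:
    deltaL1=-1/8, deltaH1=4, dL0=1, dH0=2 (basin-of-attraction example)."""
    return IncentiveParams(deltaL1=-0.125, deltaH1=4.0, dL0=1.0, dH0=2.0)


@pytest.fixture
def panel_a_incentives():
    """Both leading incentives negative: bistable edges with one saddle."""
    return IncentiveParams(deltaL1=-1.0, deltaH1=1.0, dL0=1.0, dH0=-1.0)


@pytest.fixture
def decaying():
    return DecayingResource(alpha=1.0)


@pytest.fixture
def renewing():
    return RenewingResource(r=1.0, k=1.0, q=1.0, eL=0.1, eH=0.5)


@pytest.fixture
def cycling_system(cycling_incentives, decaying):
    def make(epsilon: float) -> EcoEvoSystem:
        return EcoEvoSystem(cycling_incentives, decaying.with_epsilon(epsilon))

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_incentives(rng, scale=5.0):
    return IncentiveParams(*rng.uniform(-scale, scale, size=4))
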