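import numpy as np
import pytest

from tenmclock import DiffusionParams, KineticParams


@pytest.fixture
def fig4_kinetics() -> KineticParams:
    """Turing-regime kinetic set: gamma=2.4, m=1.6, k2=0.2, k3=0.475, k1=1."""
    return KineticParams(k1=1.0, k2=0.2, k3=0.475, gamma=2.4, m=1.6)


@pytest.fixture
def fig4_diffusion() -> DiffusionParams:
    return DiffusionParams(Dx=1.45, Dy=0.09)


@pytest.fixture
def slowdown_kinetics() -> KineticParams:
    """Slow-down protocol start: gamma=2, m=1.25, k2=0.75, k3=0.49, k1=1."""
    return KineticParams(k1=1.0, k2=0.75, k3=0.49, gamma=2.0, m=1.25)


def random_oscillator_params(rng: np.random.Generator) -> KineticParams:
    """A random valid parameter set in the oscillator-capable regime."""
    gamma = rng.uniform(1.6, 3.2)
    m = rng.uniform(0.8, gamma - 0.3)
    return KineticParams(
        k1=rng.uniform(0.4, 2.5),
        k2=rng.uniform(0.05, 1.5),
        k3=rng.uniform(0.1, 1.5),
        gamma=gamma,
        m=m,
    )
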