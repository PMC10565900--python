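import numpy as np
import pytest

from cheatcycles import ModelParams, PassageParams, SolverSettings


@pytest.fixture
def model():
    """Focal density-dependence-only parameterization (a=1, b=0)."""
    return ModelParams(a=1.0, b=0.0)


@pytest.fixture
def freq_model():
    """Frequency-dependence-only parameterization (a=0, b=1)."""
    return ModelParams(a=0.0, b=1.0)


@pytest.fixture
def neutral_model():
    """Neutral cheat: no modifiers, no benefit."""
    return ModelParams(a=0.0, b=0.0, h=1.0)


@pytest.fixture
def short_passage():
    return PassageParams(D=10.0, tgrow=10.0, n_cycles=30, burn_in_cycles=10)


@pytest.fixture
def coarse_solver():
    """Default tolerances but coarser dense sampling, for faster tests."""
    return SolverSettings(dt=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
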