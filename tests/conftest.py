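import numpy as np
import pytest
from hypothesis import settings

from reachadapt.arm import LinearArmSurrogate, default_arm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def arm():
    """One shared surrogate; construction solves the reference posture once."""
    return default_arm()


@pytest.fixture(scope="session")
def solved_90(arm):
    from reachadapt.arm import TargetSpec

    return arm.solve_inverse(TargetSpec(90.0, 0.20))


@pytest.fixture()
def linear_arm():
    """Analytic linear forward map F(p, W) = M (I + W) p used as an oracle."""
    rng = np.random.default_rng(42)
    M = rng.normal(0.0, 0.3, (2, 6))
    return LinearArmSurrogate(M)
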