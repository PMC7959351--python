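import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from weedcover import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth():
    return synthetic.default_truth()


@pytest.fixture(scope="session")
def design():
    return synthetic.StudyDesign()


@pytest.fixture(scope="session")
def obs_table(truth, design):
    """One simulated study at the default design (48 rows)."""
    return synthetic.simulate_proportions(truth, design, seed=11)


def random_admissible(rng: np.random.Generator):
    """One random coefficient vector satisfying the positive-growth
    constraints (rejection sampling on the slope sums)."""
    from weedcover.betareg import BetaRegParams

    while True:
        a0, a1, a2 = rng.normal(0, 2, size=3)
        b0 = abs(rng.normal(0.6, 0.4)) + 1e-3
        b1, b2 = rng.normal(0, 0.5, size=2)
        if b0 + b1 > 0 and b0 + b2 > 0:
            g0, g1 = rng.normal(2, 1), rng.normal(0, 0.2)
            return BetaRegParams(a0, a1, a2, b0, b1, b2, g0, g1)
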