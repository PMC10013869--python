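import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from burstinfo import CircuitSpec, Concentrations, RateParameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_rate_params(rng: np.random.Generator, spread: float = 1.5) -> RateParameters:
    """Log-uniform draw of basal rates and interaction factors.

    ``spread`` is the half-width in decades; the activator constraint
    (eta_ab >= 1, eta_ib <= 1) is respected.
    """
    def lu(lo, hi):
        return 10.0 ** rng.uniform(lo, hi)

    return RateParameters(
        k_b=lu(-spread, spread),
        k_u=lu(-spread, spread),
        k_a=lu(-spread, spread),
        k_i=lu(-spread, spread),
        eta_ab=lu(0, spread),
        eta_ib=lu(-spread, 0),
        eta_ua=lu(-spread, spread),
        eta_ba=lu(-spread, spread),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230302)


@pytest.fixture
def four_spec():
    return CircuitSpec()


@pytest.fixture
def six_spec():
    return CircuitSpec(include_noncognate=True)


@pytest.fixture
def midpoint():
    return Concentrations()
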