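import numpy as np
import pytest

from waneboost import canonical_model, solve_fixed_point
from waneboost.stationary import stationary_process_density


@pytest.fixture(scope="session")
def canonical():
    """The canonical parameter set: lam=1.5, w=1, sigma1=2, sigma2=1, y_b=4,
    for which y_c = 1, f(y_c) = 4, f(f(y_c)) = 6.25, delta = 2."""
    return canonical_model()


@pytest.fixture(scope="session")
def stationary_result(canonical):
    """Normalized post-jump density phi plus time-stationary psi (shared
    across tests; the solver is deterministic)."""
    return stationary_process_density(canonical, solve_fixed_point(canonical))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
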