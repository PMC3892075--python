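import numpy as np
import pytest

from mibgtools import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def uniform_study():
    """Noise-free phantom with identical activity in all 17 segments at
    both time points."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def graded_spec():
    """Noise-free phantom with distinct, moderately graded segment
    activities (all above the wall-membership threshold) and a known
    heterogeneous washout."""
    rng = np.random.default_rng(42)
    early = 800.0 * rng.uniform(0.7, 1.0, size=17)
    late = early * rng.uniform(0.6, 0.85, size=17)
    return PhantomSpec(
        segment_activity_early=tuple(early),
        segment_activity_late=tuple(late),
    )


@pytest.fixture(scope="session")
def graded_study(graded_spec):
    return make_phantom(graded_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
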