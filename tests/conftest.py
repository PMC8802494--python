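import numpy as np
import pytest

from crosshaz import SurvivalSample, preset, simulate_sample


@pytest.fixture
def toy_two_subjects():
    """Arm-1 event at t=1, arm-2 event at t=2: log-rank Z=0.5, V=0.25."""
    return SurvivalSample([1.0, 2.0], [1, 1], [1, 2])


@pytest.fixture
def six_subjects():
    """n1=n2=3 with distinct times: C(6,3)=20 label assignments."""
    return SurvivalSample([1.0, 2.5, 4.0, 1.5, 3.0, 5.0],
                          [1, 1, 1, 1, 0, 1],
                          [1, 1, 1, 2, 2, 2])


@pytest.fixture
def null_sample():
    """Identical exponential arms with uniform censoring, n=150/arm."""
    return simulate_sample(preset("null", n_per_arm=150),
                           rng=np.random.default_rng(2024))


def random_sample(rng, n_per_arm=40, censor_frac=0.3):
    """Small random two-arm sample for property tests."""
    n = 2 * n_per_arm
    t = rng.exponential(1.0, n)
    c = rng.exponential(1.0 / censor_frac, n) if censor_frac > 0 else np.full(n, np.inf)
    obs = np.minimum(t, c)
    status = (t <= c).astype(int)
    group = np.repeat([1, 2], n_per_arm)
    return SurvivalSample(np.maximum(obs, 1e-9), status, group)
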