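import numpy as np
import pytest

from survcut import CohortConfig, SurvivalSample, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240805)


def random_sample(rng, n=None, censor_frac=0.3, max_time=50.0, tie_prob=0.3):
    """Random survival sample with occasional ties."""
    n = n or int(rng.integers(3, 40))
    t = rng.uniform(0.5, max_time, size=n)
    if rng.random() < tie_prob and n >= 4:
        t[: n // 2] = np.round(t[: n // 2])  # manufacture ties
    e = (rng.random(n) > censor_frac).astype(int)
    return SurvivalSample(time=t, event=e)


@pytest.fixture
def effect_cohort():
    """Synthetic cohort with a planted threshold effect (HR 3)."""
    return generate_cohort(CohortConfig(n=200, hazard_ratio=3.0, seed=42))


@pytest.fixture
def null_cohort():
    """Synthetic cohort with no marker effect."""
    return generate_cohort(CohortConfig(n=67, hazard_ratio=1.0, seed=43))
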