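import numpy as np
import pandas as pd
import pytest

from fsindex.synthetic import AuxiliarySpec, CampaignConfig, generate_campaign


@pytest.fixture(scope="session")
def small_campaign():
    """A small structured campaign reused across tests."""
    return generate_campaign(CampaignConfig(n_samples=300, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_limit_triples(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random admissible (T, min, max) triples covering all limit kinds."""
    kind = rng.integers(0, 4, size=n)
    base = 10.0 ** rng.uniform(-2, 2, size=n)
    mn = np.zeros(n)
    mx = base.copy()
    band = kind == 1
    mn[band] = base[band] * rng.uniform(0.05, 0.95, size=band.sum())
    point = kind == 2
    mn[point] = base[point]
    zero = kind == 3
    mn[zero] = 0.0
    mx[zero] = 0.0
    T = np.abs(rng.normal(0.0, 1.5, size=n)) * np.where(mx > 0, mx, 1.0)
    T[rng.random(n) < 0.05] = 0.0  # exercise the T == 0 edges
    return pd.DataFrame({"T": T, "mn": mn, "mx": mx})
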