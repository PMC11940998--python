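import numpy as np
import pytest

import sersclass as sc

# A coarse grid keeps generator/protocol tests fast; the full 1950-point
# default grid is exercised where the predictor count itself is the check.
SMALL_AXIS = sc.WavenumberAxis(start=517.0, end=1913.0, n_points=400)


@pytest.fixture
def small_axis() -> sc.WavenumberAxis:
    return SMALL_AXIS


@pytest.fixture
def small_cohort() -> sc.SpectraDataset:
    cfg = sc.SyntheticConfig(
        axis=SMALL_AXIS,
        classes=(("respiratory", 8, 3), ("referent", 12, 3)),
        seed=42,
    )
    return sc.generate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_xy(rng: np.random.Generator, n: int = 12, p: int = 6, informative: int | None = 0):
    """Random predictors with an optional informative column tied to y."""
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.normal(size=(n, p))
    if informative is not None:
        X[:, informative] = y + 0.05 * rng.normal(size=n)
    return X, y
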