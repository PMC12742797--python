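import numpy as np
import pytest

from chdrisk.cohort import Cohort
from chdrisk.simulate import CohortSpec, generate


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """2,000-row cohort at the default 9.42% prevalence."""
    return generate(CohortSpec(n=2000, seed=101))


@pytest.fixture(scope="session")
def tiny_cohort() -> Cohort:
    return generate(CohortSpec(n=400, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def toy_cohort(X: np.ndarray, y: np.ndarray, kinds: list[str] | None = None) -> Cohort:
    """Wrap a raw matrix/labels pair in a Cohort with generic metadata."""
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    return Cohort(
        X,
        np.asarray(y, dtype=int),
        [f"x{j}" for j in range(d)],
        kinds or ["continuous"] * d,
        ["clinical"] * d,
    )
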