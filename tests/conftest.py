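import numpy as np
import pytest

from metabosig import SyntheticSpec, default_panel, generate_cohort
from metabosig.preprocess import FeatureTable


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (38 O / 36 P) with ground truth."""
    return generate_cohort(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for I/O round-trip tests."""
    return generate_cohort(SyntheticSpec(n_O=4, n_P=4, seed=3, missing_rate=0.0))


def make_class_table(
    seed, n_per=40, n_noise=50, n_informative=0, effect=1.5, features=None
):
    """Autoscaled random table with optional planted class-separating columns."""
    rng = np.random.default_rng(seed)
    n, p = 2 * n_per, n_noise + n_informative
    X = rng.standard_normal((n, p))
    X[:n_per, :n_informative] += effect
    y = np.array(["a"] * n_per + ["b"] * n_per, dtype=object)
    if features is None:
        features = [f"inf{i}" for i in range(n_informative)] + [
            f"noise{i}" for i in range(n_noise)
        ]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return FeatureTable(
        X=X, features=features, y=y, level="V1",
        sample_ids=[f"s{i}" for i in range(n)],
        response_name="class", y_kind="class",
    )


def make_regression_table(seed, n=60, p=10, noise=0.1, coefs=None):
    """Random table with continuous response y = X b + noise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    b = np.zeros(p) if coefs is None else np.asarray(coefs, dtype=float)
    if coefs is None:
        b[: min(3, p)] = [1.0, -0.5, 0.25][: min(3, p)]
    y = X @ b + noise * rng.standard_normal(n)
    return FeatureTable(
        X=X, features=[f"f{i}" for i in range(p)], y=y, level="V1",
        sample_ids=[f"s{i}" for i in range(n)],
        response_name="y", y_kind="continuous",
    )
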