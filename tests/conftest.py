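import numpy as np
import pytest

from rankstab import FeatureTable, SyntheticSpec, fixture_suite, generate


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def small_synthetic():
    """200 x 100 table with planted signal, shared across read-only tests."""
    spec = SyntheticSpec(
        n_samples=200, n_features=100, n_signal=5, signal_effect=1.5,
        n_high_variance=5, n_duplicate_pairs=3, missing_rate=0.02, seed=0,
    )
    return generate(spec)


def make_table(values, names=None, outcome=None) -> FeatureTable:
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    if outcome is None:
        outcome = np.zeros(values.shape[0], dtype=int)
        outcome[: values.shape[0] // 2] = 1
    return FeatureTable(
        values=values,
        feature_names=list(names),
        column_order={f: i for i, f in enumerate(names)},
        outcome=np.asarray(outcome),
    )


def random_table(rng: np.random.Generator, n: int, p: int, ties: bool = False) -> FeatureTable:
    X = rng.standard_normal((n, p))
    if ties:
        X = np.round(X)  # integer quantization -> heavy score ties
    y = np.zeros(n, dtype=int)
    n_pos = max(1, int(0.2 * n))
    y[rng.permutation(n)[:n_pos]] = 1
    return make_table(X, [f"g{i:03d}" for i in range(p)], y)
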