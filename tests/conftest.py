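import numpy as np
import pytest

from pequal import FeatureTable


def random_table(rng: np.random.Generator, n: int | None = None) -> FeatureTable:
    """A random valid table: positive areas, p_i = a_i * U_i, at least one p > 0."""
    if n is None:
        n = int(rng.integers(2, 31))
    areas = rng.gamma(shape=2.0, scale=500.0, size=n) + 1e-6
    protected = areas * rng.uniform(0.0, 1.0, size=n)
    i = int(rng.integers(n))
    protected[i] = areas[i] * 0.5  # guarantee some protection
    return FeatureTable.from_arrays(areas, protected)


def gini_pairwise(values) -> float:
    """Independent Gini oracle: G = sum_ij |x_i - x_j| / (2 N^2 mean)."""
    x = np.asarray(values, dtype=float)
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * x.size**2 * x.mean()))


@pytest.fixture
def rng():
    return np.random.default_rng(20170215)
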