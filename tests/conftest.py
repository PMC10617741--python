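import numpy as np
import pytest

from fallrisk import FeatureTable, VariableSpec


def make_table(values, domains=None, group=None, names=None, mask=None):
    """Small helper building a FeatureTable from a plain array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if domains is None:
        domains = ["gait"] * p
    if names is None:
        names = [f"v{j + 1}" for j in range(p)]
    if group is None:
        half = n // 2
        group = ["faller"] * half + ["non_faller"] * (n - half)
    specs = [VariableSpec(nm, dom) for nm, dom in zip(names, domains)]
    ids = [f"P{i + 1:03d}" for i in range(n)]
    return FeatureTable(ids, list(group), specs, values, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def signal_table(rng):
    """n=60 cohort, one strongly separating variable + 9 noise variables."""
    n1, n2 = 21, 39
    x = rng.standard_normal((n1 + n2, 10))
    x[:n1, 0] += 6.0  # fully separated group shift on the first variable
    return make_table(
        x,
        group=["faller"] * n1 + ["non_faller"] * n2,
        domains=["gait"] * 10,
    )
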