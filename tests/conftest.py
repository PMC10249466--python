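import numpy as np
import pandas as pd
import pytest

from tmrnet import VariableGroup, align_dataset


def make_group(name, role, values, samples=None, variables=None, meta=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"m{i + 1}" for i in range(values.shape[0])]
    variables = variables or [f"v{j + 1}" for j in range(values.shape[1])]
    return VariableGroup(
        name=name, role=role,
        data=pd.DataFrame(values, index=samples, columns=variables),
        meta=dict(meta or {}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230505)


@pytest.fixture
def small_dataset(rng):
    """Treatment + two measured + response groups over 60 samples, with one
    planted cross-omics effect v = 3u + noise(sd 0.5)."""
    n = 60
    samples = [f"m{i + 1:02d}" for i in range(n)]
    treated = np.zeros(n)
    treated[rng.permutation(n)[: n // 2]] = 1.0
    weight = 45 + 3 * rng.normal(size=n)
    tgroup = make_group("treatments", "treatment",
                        np.column_stack([treated, weight]),
                        samples, ["treated", "weight"])
    u = rng.normal(size=n)
    a = make_group("omics_a", "measured",
                   np.column_stack([u] + [rng.normal(size=n) for _ in range(3)]),
                   samples, ["u", "a2", "a3", "a4"])
    v = 3.0 * u + 0.5 * rng.normal(size=n)
    b = make_group("omics_b", "measured",
                   np.column_stack([v] + [rng.normal(size=n) for _ in range(2)]),
                   samples, ["v", "b2", "b3"])
    resp = make_group("outcome", "response",
                      rng.normal(size=(n, 2)), samples, ["r1", "r2"])
    return align_dataset([tgroup, a, b, resp])
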