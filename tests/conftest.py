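import numpy as np
import pandas as pd
import pytest

from tcf.cohort import CohortTable, ColumnSpec


def make_table(features: dict, y, kinds: dict | None = None) -> CohortTable:
    """Build a cohort table from plain dicts; kinds default to continuous."""
    kinds = kinds or {}
    specs = [ColumnSpec(n, kinds.get(n, "continuous")) for n in features]
    specs.append(ColumnSpec("death28", "boolean", role="outcome"))
    frame = pd.DataFrame({n: np.asarray(v, dtype=float) for n, v in features.items()})
    frame["death28"] = np.asarray(y, dtype=float)
    return CohortTable(specs, frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort(rng) -> CohortTable:
    """Complete 60-patient cohort with one informative feature."""
    n = 60
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    b = rng.binomial(1, 0.4, n)
    y = (x1 + 0.5 * rng.standard_normal(n) > 0.6).astype(float)
    return make_table({"x1": x1, "x2": x2, "flag": b}, y, kinds={"flag": "boolean"})
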