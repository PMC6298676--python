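import numpy as np
import pandas as pd
import pytest

from slemod.data import ExpressionSet, SampleMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_eset(values, dataset_id="D1", cohorts=None, sledai=None, row_level="gene", prefix="s"):
    """Build an ExpressionSet from a 2-D array (genes x samples)."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    ids = [f"{dataset_id}_{prefix}{i:03d}" for i in range(n)]
    if cohorts is None:
        cohorts = ["HC"] * n
    if sledai is None:
        sledai = [0.0 if c == "HC" else (3.0 if c == "SLE_inactive" else 10.0) for c in cohorts]
    metas = [
        SampleMeta(sample_id=s, dataset_id=dataset_id, cohort=c, sledai=v)
        for s, c, v in zip(ids, cohorts, sledai)
    ]
    frame = pd.DataFrame(values, index=[f"G{i:04d}" for i in range(g)], columns=ids)
    return ExpressionSet(frame, metas, row_level=row_level)


@pytest.fixture
def small_eset(rng):
    return make_eset(rng.normal(7, 1, (20, 10)))
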