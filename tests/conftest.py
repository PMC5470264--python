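import numpy as np
import pandas as pd
import pytest

from tsswitch import ExpressionMatrix, SampleDesign


def make_design(time_points, n_replicates=3):
    samples = tuple(
        (f"{tp}_r{r}", tp, k, r)
        for k, tp in enumerate(time_points)
        for r in range(1, n_replicates + 1)
    )
    return SampleDesign(samples)


def make_matrix(values_by_tss, design, unit="tpm"):
    """Build an ExpressionMatrix from {tss_id: row values in design order}."""
    df = pd.DataFrame.from_dict(values_by_tss, orient="index", dtype=float)
    df.columns = design.sample_ids
    return ExpressionMatrix(df, design, unit=unit)


@pytest.fixture
def two_point_design():
    return make_design(["t1", "t2"], n_replicates=3)


@pytest.fixture
def twelve_point_design():
    tps = ["E11", "E12", "E13", "E14", "E15", "E16", "E17", "E18",
           "P0", "P3", "P6", "P9"]
    return make_design(tps, n_replicates=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
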