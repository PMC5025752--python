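import numpy as np
import pandas as pd
import pytest

from panconet.io_formats import ExpressionMatrix, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_counts(rng):
    """A 50-gene × 8-sample count matrix with moderate depth variation."""
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"S{j}" for j in range(8)]
    base = rng.uniform(20, 500, size=(50, 1))
    depth = rng.uniform(0.5, 2.0, size=8)
    values = rng.poisson(base * depth)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "counts")


@pytest.fixture
def two_group_samples():
    """Sample table: one cancer with 6 tumors and 5 normals."""
    rows = []
    for i in range(6):
        rows.append((f"T{i}", f"P{i}", "CA", "tumor"))
    for i in range(5):
        rows.append((f"N{i}", f"P{i+10}", "CA", "normal"))
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "patient_id", "cancer_type", "tissue_status"])
    )
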