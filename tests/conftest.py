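import numpy as np
import pandas as pd
import pytest

from dmne import ExpressionMatrix, SampleMetadata, SyntheticConfig, generate


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with easy numbers."""
    return ExpressionMatrix(
        ["G1", "G2", "G3"],
        ["S1", "S2", "S3", "S4"],
        np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [4.0, 5.0, 6.0, 7.0],
                [1.0, 0.0, 1.0, 0.0],
            ]
        ),
    )


@pytest.fixture
def small_config():
    """Desk-size planted-module configuration for fast end-to-end tests."""
    return SyntheticConfig(
        m=60, n_ref=12, n_case_per_stage=4, stages=4, critical_stage=2,
        module_size=10, seed=42,
    )


@pytest.fixture
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture
def metadata_frame():
    rows = [{"sample_id": f"R{i}", "cohort": "reference", "stage": 0} for i in range(4)]
    rows += [
        {"sample_id": f"C{s}{i}", "cohort": "case", "stage": s}
        for s in (1, 2, 3)
        for i in range(2)
    ]
    return pd.DataFrame(rows)
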