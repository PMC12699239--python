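import numpy as np
import pandas as pd
import pytest

from mirnapanel.io import CtRecord, RunConfig, SampleAnnotation
from mirnapanel.relquant import ExpressionMatrix


@pytest.fixture
def toy_sheet():
    """Two benign + two malignant validation samples."""
    return [
        SampleAnnotation("B1", "benign", "validation"),
        SampleAnnotation("B2", "benign", "validation"),
        SampleAnnotation("M1", "malignant", "validation"),
        SampleAnnotation("M2", "malignant", "validation"),
    ]


@pytest.fixture
def toy_records():
    """Single-replicate Ct table: one target, one reference, four samples.

    Target dCt: benign 7 and 7, malignant 5 and 5 (reference Ct 20
    everywhere), so malignant relative expression is exactly 4.
    """
    rows = [
        ("B1", "REF", 20.0), ("B2", "REF", 20.0),
        ("M1", "REF", 20.0), ("M2", "REF", 20.0),
        ("B1", "miR-X", 27.0), ("B2", "miR-X", 27.0),
        ("M1", "miR-X", 25.0), ("M2", "miR-X", 25.0),
    ]
    return [CtRecord(s, a, 1, ct) for s, a, ct in rows]


@pytest.fixture
def toy_config():
    return RunConfig(reference_assay_ids=["REF"])


def make_expression_matrix(values, sample_ids=None, assay_ids=None, **kwargs):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"S{i+1}" for i in range(values.shape[0])]
    assay_ids = assay_ids or [f"A{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=sample_ids, columns=assay_ids),
                            **kwargs)
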