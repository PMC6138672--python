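import numpy as np
import pandas as pd
import pytest

from trapclient.io import LINEAR, LOG2, AbundanceMatrix, SampleDesign


def make_matrix(values, protein_ids=None, sample_ids=None, scale=LOG2):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    protein_ids = protein_ids or [f"P{i:03d}" for i in range(m)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    return AbundanceMatrix(
        pd.DataFrame(values, index=protein_ids, columns=sample_ids), scale
    )


def make_design(groups, control):
    """groups: dict group -> list of sample ids."""
    rows = []
    for g, samples in groups.items():
        for r, s in enumerate(samples, start=1):
            rows.append({"sample_id": s, "group": g, "replicate": r})
    table = pd.DataFrame(rows).set_index("sample_id")
    return SampleDesign(table, control=control)


@pytest.fixture
def small_design():
    return make_design(
        {
            "control": ["c1", "c2", "c3"],
            "siRNA1": ["a1", "a2", "a3"],
            "siRNA2": ["b1", "b2", "b3"],
        },
        control="control",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
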