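import numpy as np
import pandas as pd
import pytest

from panploid.containers import CountMatrix, OrthogroupMatrix


@pytest.fixture
def tiny_matrix() -> OrthogroupMatrix:
    """3 accessions; c1 in all, c2 in acc1+acc2, c3 in acc3 only."""
    counts = pd.DataFrame(
        {"acc1": [1, 1, 0], "acc2": [1, 1, 0], "acc3": [1, 0, 1]},
        index=["c1", "c2", "c3"],
    )
    return OrthogroupMatrix(counts)


def make_count_matrix(counts: np.ndarray, genes, samples, tissues, reps):
    sheet = pd.DataFrame(
        {"tissue": tissues, "replicate": reps},
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), sheet)
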