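import numpy as np
import pytest

from scensus.io import ExpressionMatrix, PartitionLabels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs in 2-D with ground-truth labels."""
    gen = np.random.default_rng(7)
    a = gen.normal(loc=(0.0, 0.0), scale=0.5, size=(30, 2))
    b = gen.normal(loc=(8.0, 8.0), scale=0.5, size=(30, 2))
    feats = np.vstack([a, b])
    labels = ["a"] * 30 + ["b"] * 30
    cells = [f"c{i}" for i in range(60)]
    return feats, PartitionLabels(cell_ids=cells, labels=labels, method_name="truth")


@pytest.fixture
def tiny_counts():
    return ExpressionMatrix(
        values=np.array([[1.0, 3.0], [2.0, 2.0], [5.0, 0.0]]),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2"],
    )


def make_partition(labels, prefix="c", method="m"):
    return PartitionLabels(
        cell_ids=[f"{prefix}{i}" for i in range(len(labels))],
        labels=list(labels),
        method_name=method,
    )
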