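import numpy as np
import pytest

from radharmony import BatchDesign, FeatureTable


@pytest.fixture
def toy_ab():
    """Two batches of one feature: A = {1,2,3}, B = {11,12,13}."""
    table = FeatureTable(
        [f"s{i}" for i in range(6)],
        ["f"],
        np.array([[1.0], [2.0], [3.0], [11.0], [12.0], [13.0]]),
    )
    design = BatchDesign(labels=np.array(["A"] * 3 + ["B"] * 3), reference_label="A")
    return table, design


def random_table(seed, n_per_batch=(8, 6), n_features=4, scale=1.0):
    """Small random multi-batch table for property checks."""
    rng = np.random.default_rng(seed)
    n = sum(n_per_batch)
    values = rng.normal(0.0, scale, size=(n, n_features))
    for i, sz in enumerate(n_per_batch):
        lo = sum(n_per_batch[:i])
        values[lo : lo + sz] += rng.normal(0.0, 2.0, size=n_features)
    labels = np.concatenate(
        [np.repeat(f"b{i}", sz) for i, sz in enumerate(n_per_batch)]
    )
    table = FeatureTable(
        [f"s{i}" for i in range(n)], [f"f{j}" for j in range(n_features)], values
    )
    return table, BatchDesign(labels=labels)
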