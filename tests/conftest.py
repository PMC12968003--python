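import numpy as np
import pandas as pd
import pytest

from succnet import OtuTable, generate_chronosequence


def make_table(counts, groups=None, kingdom="bacteria", phyla=None):
    """Small handmade OtuTable helper."""
    counts = np.asarray(counts)
    n, m = counts.shape
    sample_ids = [f"s{i}" for i in range(n)]
    otu_ids = [f"o{j}" for j in range(m)]
    groups = groups or ["g1"] * n
    metadata = {s: {"group": g, "replicate": i % 5 + 1, "kingdom": kingdom}
                for i, (s, g) in enumerate(zip(sample_ids, groups))}
    phyla = phyla or ["PhylumA"] * m
    taxonomy = {o: {"phylum": p} for o, p in zip(otu_ids, phyla)}
    return OtuTable(counts=counts, sample_ids=sample_ids, otu_ids=otu_ids,
                    taxonomy=taxonomy, metadata=metadata)


@pytest.fixture(scope="session")
def synth_default():
    """One default synthetic chronosequence (55 samples, strong separation)."""
    return generate_chronosequence(seed=7)


@pytest.fixture
def tiny_table():
    return make_table([[2, 3, 5, 0],
                       [1, 1, 1, 1],
                       [0, 4, 4, 2]])


def two_blob_distances(n_per=10, sep=10.0, seed=0, extra_midpoint=False):
    """Euclidean distance matrix of two well-separated Gaussian blobs."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, 2))
    b = rng.normal(sep, 1.0, size=(n_per, 2))
    pts = np.vstack([a, b])
    if extra_midpoint:
        pts = np.vstack([pts, [[sep / 2.0, sep / 2.0]]])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    ids = [f"p{i}" for i in range(len(pts))]
    return pd.DataFrame(d, index=ids, columns=ids)
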