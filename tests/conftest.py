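import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance_map(rng, shape=(16, 16), n_blobs=4, with_classes=False):
    """Random instance map built from rectangular blobs (later blobs overwrite)."""
    labels = np.zeros(shape, dtype=np.int32)
    for k in range(1, n_blobs + 1):
        h = rng.integers(2, shape[0] // 2 + 1)
        w = rng.integers(2, shape[1] // 2 + 1)
        y = rng.integers(0, shape[0] - h + 1)
        x = rng.integers(0, shape[1] - w + 1)
        labels[y:y + h, x:x + w] = k
    ids = np.unique(labels[labels > 0])
    # relabel contiguously so ids are 1..n
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, 1):
        out[labels == old] = new
    classes = None
    if with_classes:
        classes = {int(i): ("positive" if rng.random() < 0.5 else "negative")
                   for i in np.unique(out[out > 0])}
    return out, classes
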