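import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for reference_impl

from segfuse import MultiClassSegmentation


@pytest.fixture
def eye_affine():
    return np.eye(4)


def make_seg(values, affine=None, label_set=(1, 2, 4)):
    """Build a segmentation from a nested list / 1-D sequence (as 1x1xN)."""
    arr = np.asarray(values, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr.reshape(1, 1, -1)
    if affine is None:
        affine = np.eye(4)
    return MultiClassSegmentation(arr, affine, frozenset(label_set))


@pytest.fixture
def seg_factory():
    return make_seg


@pytest.fixture
def small_phantom():
    """A small, quick phantom ground truth shared across tests."""
    from segfuse import PhantomParams, generate_phantom

    return generate_phantom(
        PhantomParams(
            shape=(32, 32, 20),
            edema_radii=(10.0, 8.0, 6.0),
            core_radii=(6.0, 5.0, 4.0),
            necrosis_radii=(3.0, 2.5, 2.0),
            seed=11,
        )
    )
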