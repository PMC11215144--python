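import numpy as np
import pytest

from earcount import BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_box(rng, frame=(768, 432), w_range=(4.0, 40.0), h_range=(4.0, 40.0)):
    return BoundingBox(
        cx=float(rng.uniform(0, frame[0])),
        cy=float(rng.uniform(0, frame[1])),
        w=float(rng.uniform(*w_range)),
        h=float(rng.uniform(*h_range)),
    )
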