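import numpy as np
import pytest

from casimac import LabeledDataset, TransformConfig
from casimac.benchmark import make_quadrant_task, make_ternary_toy


@pytest.fixture(scope="session")
def ternary_toy():
    return make_ternary_toy(seed=0)


@pytest.fixture(scope="session")
def quadrant_task_small():
    """One quadrant task with a small test set, for fast end-to-end checks."""
    return make_quadrant_task(seed=7, d_train=40, t_test=200)


@pytest.fixture
def line_fixture():
    """Hand-worked 1-D binary problem: class 1 at {0, 1}, class 2 at {3}.

    With alpha=0, beta=1, k=1 the latent targets are the signed distances to
    the closest opposite-class neighbor: (-3, -2, +2).
    """
    ds = LabeledDataset(points=[[0.0], [1.0], [3.0]], labels=[1, 1, 2])
    cfg = TransformConfig(alpha=0.0, beta=1.0, k_alpha=1, k_beta=1)
    return ds, cfg, np.array([-3.0, -2.0, 2.0])
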