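import numpy as np
import pytest

from boostdiff.difftree import BASELINE, TARGET, LearningSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_learning_pair(rng, n_t=12, n_b=12, p=6):
    """Random unstructured two-condition learning sets."""
    regs = [f"R{i}" for i in range(p)]
    ls_t = LearningSet(rng.normal(size=(n_t, p)), rng.normal(size=n_t), regs, TARGET)
    ls_b = LearningSet(rng.normal(size=(n_b, p)), rng.normal(size=n_b), regs, BASELINE)
    return ls_t, ls_b


def planted_learning_pair(rng, n=60, p=5, noise=0.1):
    """Target response driven by regulator 0 in the target condition only.

    Both responses have comparable scale (as after pooled unit-variance
    scaling): the baseline response is pure unit-variance noise.
    """
    regs = [f"R{i}" for i in range(p)]
    xt = rng.normal(size=(n, p))
    xb = rng.normal(size=(n, p))
    yt = xt[:, 0] + noise * rng.normal(size=n)
    yb = rng.normal(size=n)
    return (
        LearningSet(xt, yt, regs, TARGET),
        LearningSet(xb, yb, regs, BASELINE),
    )
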