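import numpy as np
import pytest

from dhrls import AssociationMatrix, KernelMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd_kernel(rng, n, name="K", side="disease"):
    A = rng.standard_normal((n, n))
    return KernelMatrix(A @ A.T / n + np.eye(n), name=name, side=side)


def random_association(rng, n, m, p=0.3):
    values = (rng.random((n, m)) < p).astype(float)
    # guarantee at least one edge so ideal kernels are nonzero
    if values.sum() == 0:
        values[0, 0] = 1.0
    return AssociationMatrix(values)


@pytest.fixture
def small_Y(rng):
    return random_association(rng, 6, 5)
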