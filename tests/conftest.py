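import numpy as np
import pytest

from rggcunet import nn
from rggcunet.nn.tensor import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _seed_init():
    """Deterministic layer initialisation for every test."""
    nn.manual_seed(0)


def finite_difference_check(fn, tensors, rng, h=1e-6, tol=1e-4, n_probe=8):
    """Compare autodiff gradients of ``sum(weights * fn())`` against central
    finite differences at ``n_probe`` random coordinates of each tensor."""
    out = fn()
    weights = rng.normal(size=out.shape)
    for t in tensors:
        t.grad = None
    (out * Tensor(weights)).sum().backward()
    for t in tensors:
        grad = t.grad
        assert grad is not None, "no gradient reached a required tensor"
        flat = t.data.ravel()
        for i in rng.choice(flat.size, size=min(n_probe, flat.size),
                            replace=False):
            orig = flat[i]
            flat[i] = orig + h
            f_plus = float((fn().data * weights).sum())
            flat[i] = orig - h
            f_minus = float((fn().data * weights).sum())
            flat[i] = orig
            numeric = (f_plus - f_minus) / (2 * h)
            analytic = grad.ravel()[i]
            assert abs(numeric - analytic) <= tol * max(1.0, abs(numeric)), (
                f"gradient mismatch: numeric {numeric}, analytic {analytic}")
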