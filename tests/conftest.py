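import numpy as np
import pytest

from seu2net.nn import Tensor


def gradcheck(fn, inputs, eps=1e-5, atol=1e-4, rtol=1e-3):
    """Compare autodiff gradients of scalar ``fn(*tensors)`` with central
    finite differences (float64)."""
    tensors = [Tensor(np.asarray(x, dtype=np.float64), requires_grad=True) for x in inputs]
    out = fn(*tensors)
    out.backward()
    for ti, t in enumerate(tensors):
        num = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        nflat = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*tensors).item()
            flat[i] = orig - eps
            lo = fn(*tensors).item()
            flat[i] = orig
            nflat[i] = (hi - lo) / (2 * eps)
        np.testing.assert_allclose(
            t.grad, num, atol=atol, rtol=rtol,
            err_msg=f"analytic vs numeric gradient mismatch for input {ti}")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
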