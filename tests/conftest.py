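import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def central_difference(fn, params, step=1e-5):
    """Numerical gradient of scalar fn() w.r.t. a flat list of Tensors."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data, dtype=np.float64)
        flat = p.data.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + step
            up = fn()
            flat[i] = orig - step
            down = fn()
            flat[i] = orig
            gflat[i] = (up - down) / (2 * step)
        grads.append(g)
    return grads
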