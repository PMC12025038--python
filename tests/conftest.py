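import numpy as np
import pytest

from fssmr.network import MultiStreamCNN, NetworkSpec, SingleStreamCNN
from fssmr.phantoms import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_dataset():
    """40 phantoms, uniform class mix, fixed seed."""
    samples, manifest = generate_dataset(40, seed=3)
    return samples, manifest


@pytest.fixture()
def tiny_multi_model():
    """Two-stream model small enough for finite-difference checks."""
    spec = NetworkSpec(
        image_size=8,
        stream_channels=((3, 2), (3, 2)),
        stream_dilations=(1, 2),
        dropout_rate=0.0,
    )
    return MultiStreamCNN(spec, seed=0)


@pytest.fixture()
def tiny_single_model():
    spec = NetworkSpec(
        image_size=8,
        stream_channels=((2, 2, 2, 2),),
        stream_dilations=(1,),
        dropout_rate=0.0,
    )
    return SingleStreamCNN(spec, seed=0)


def conv2d_oracle(x, W, b, dilation=1):
    """Nested-loop stride-1 'same' cross-correlation, NCHW."""
    n, cin, h, w = x.shape
    cout, _, k, _ = W.shape
    ke = (k - 1) * dilation + 1
    pad = (ke - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((n, cout, h, w))
    for nn in range(n):
        for co in range(cout):
            for r in range(h):
                for c in range(w):
                    acc = 0.0
                    for ci in range(cin):
                        for i in range(k):
                            for j in range(k):
                                acc += (
                                    W[co, ci, i, j]
                                    * xp[nn, ci, r + i * dilation, c + j * dilation]
                                )
                    out[nn, co, r, c] = acc + b[co]
    return out


def maxpool_oracle(a, window=2):
    """Exhaustive per-window max scan with floor division."""
    h, w = a.shape
    ho, wo = h // window, w // window
    out = np.zeros((ho, wo))
    for r in range(ho):
        for c in range(wo):
            out[r, c] = a[r * window:(r + 1) * window,
                          c * window:(c + 1) * window].max()
    return out
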