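import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def smoke_dir(tmp_path_factory):
    """The 24-scene 128x128 smoke corpus, generated once per session."""
    from mvdnet import smoke_corpus

    d = tmp_path_factory.mktemp("smoke_corpus")
    smoke_corpus(d, master_seed=7)
    return d


@pytest.fixture(scope="session")
def smoke(smoke_dir):
    from mvdnet import load_corpus

    return load_corpus(smoke_dir)


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """A six-scene 64x64 corpus for fast training-loop tests."""
    from mvdnet.synth import SceneConfig, generate_corpus

    d = tmp_path_factory.mktemp("tiny_corpus")
    cfg = SceneConfig(width=64, height=64)
    return generate_corpus(cfg, 6, 1, 1, 11, d)


def naive_correlate2d(x: np.ndarray, kernel: np.ndarray, dilation: int = 1) -> np.ndarray:
    """Independent dense cross-correlation oracle with symmetric zero
    padding that preserves the input size (odd kernels only)."""
    kh, kw = kernel.shape
    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2
    xp = np.pad(x, ((ph, ph), (pw, pw)))
    h, w = x.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * xp[i + a * dilation, j + b * dilation]
            out[i, j] = acc
    return out


def numerical_gradient(loss_fn, array: np.ndarray, indices, eps: float = 1e-6):
    """Central-difference gradient of ``loss_fn()`` w.r.t. selected flat
    indices of ``array`` (perturbed in place)."""
    flat = array.reshape(-1)
    grads = {}
    for i in indices:
        old = flat[i]
        flat[i] = old + eps
        lp = loss_fn()
        flat[i] = old - eps
        lm = loss_fn()
        flat[i] = old
        grads[i] = (lp - lm) / (2 * eps)
    return grads
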