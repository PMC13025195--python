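import numpy as np
import pytest

from ictd.synthetic import SyntheticSpec, generate_dual_modality


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """4-class, 10-subject, well-separated dual-view dataset (n=500)."""
    spec = SyntheticSpec(n_classes=4, n_subjects=10, trials_per_subject=50,
                         class_separation=8.0, noise_sd=(0.5, 0.5), seed=7)
    return generate_dual_modality(spec)


def finite_difference_grad(f, x, h=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + h
        fp = f(x)
        flat[i] = old - h
        fm = f(x)
        flat[i] = old
        gf[i] = (fp - fm) / (2 * h)
    return g
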