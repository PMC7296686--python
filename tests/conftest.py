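import numpy as np
import pytest

from fmkldr.kernels import KernelSpec, KernelStack
from fmkldr.preprocess import FeatureMatrix


def random_feature_matrix(rng, n_samples, n_features, prefix="f"):
    return FeatureMatrix(
        rng.normal(size=(n_samples, n_features)),
        [f"s{i}" for i in range(n_samples)],
        [f"{prefix}{j}" for j in range(n_features)],
    )


def random_psd_stack(rng, n_samples, n_kernels):
    """A stack of random Gram matrices (X X^T), guaranteed symmetric PSD."""
    kernels, specs = [], []
    for m in range(n_kernels):
        X = rng.normal(size=(n_samples, n_samples + 2))
        kernels.append(X @ X.T)
        specs.append(KernelSpec("linear", {"offset": 0.0}, f"view{m}"))
    return KernelStack(kernels, specs, [f"s{i}" for i in range(n_samples)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
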