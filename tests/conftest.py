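import numpy as np
import pytest

from latentreplay.datasets import DomainSpec


def small_specs(n_domains=2, seed=0, n_train=30, n_test=10, dim=4, n_classes=3,
                shift=0.0):
    """Tiny, fast domain specs for unit tests."""
    means = np.zeros((n_classes, dim))
    for c in range(n_classes):
        means[c, c % dim] = 5.0
    specs = []
    for t in range(n_domains):
        sv = np.zeros(dim)
        sv[-1] = shift * t
        specs.append(
            DomainSpec(
                domain_id=f"dom{t}",
                n_train_per_class=n_train,
                n_test_per_class=n_test,
                class_means=means,
                class_scales=np.ones(n_classes),
                shift_vector=sv,
                rotation_angle=0.0,
                seed=seed + t,
            )
        )
    return specs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_latents(rng):
    """Two well-separated Gaussian blobs with known means."""
    a = rng.normal([-8.0, 0.0], 0.5, size=(40, 2))
    b = rng.normal([8.0, 0.0], 0.5, size=(40, 2))
    return a, b
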