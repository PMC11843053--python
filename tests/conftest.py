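import numpy as np
import pytest

from fedseg.phantoms import SiteProfile, generate_partitioned_cohort
from fedseg.training import init_weights
from fedseg.unet import ModelConfig


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest sensible U-Net: depth 1, 2 filters, 16x16 grid — used by
    structural tests where learning quality is irrelevant."""
    return ModelConfig(depth=1, base_filters=2, input_shape=(16, 16))


@pytest.fixture(scope="session")
def default_model_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def easy_profile():
    """Low-noise, high-contrast site: learnable in a few hundred steps."""
    return SiteProfile(
        site_id="easy",
        n_patients=25,
        seed=11,
        noise_sd=2.0,
        tumor_radius_range=(5.0, 9.0),
    )


@pytest.fixture(scope="session")
def easy_cohort(easy_profile):
    return generate_partitioned_cohort([easy_profile], split_fraction=0.8)


@pytest.fixture(scope="session")
def default_weights(default_model_config):
    return init_weights(default_model_config, seed=0, task_id="t")


def random_weightset(rng: np.random.Generator, n_entries=None, meta=None):
    """Small random weight set with a random manifest (shared fuzz helper)."""
    from fedseg.weights import WeightMeta, WeightSet

    n_entries = n_entries or int(rng.integers(1, 5))
    entries = []
    for i in range(n_entries):
        ndim = int(rng.integers(1, 4))
        shape = tuple(int(rng.integers(1, 4)) for _ in range(ndim))
        entries.append(
            (f"layer{i}.w", rng.uniform(-1, 1, size=shape).astype(np.float32))
        )
    return WeightSet(entries, meta or WeightMeta(task_id="fuzz", n_train_samples=1))
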