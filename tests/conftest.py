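import numpy as np
import pytest

from segtemplate.imgio import SegmentationMask, Volume
from segtemplate.phantomgen import DomainSpec, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_domain():
    """A 32^3 isotropic organ domain with mild perturbations."""
    return DomainSpec(
        name="test32",
        grid_shape=(32, 32, 32),
        spacing_mm=(1.0, 1.0, 1.0),
        organ_radius_frac=0.3,
        shape_irregularity=0.1,
        noise_sd=0.05,
        bias_strength=0.2,
        contrast_gradient=0.2,
        annotation_roughness_mm=1.0,
    )


@pytest.fixture
def clean_domain():
    """Noise-free, bias-free ellipsoid domain (all perturbations off)."""
    return DomainSpec(
        name="clean",
        grid_shape=(32, 32, 32),
        organ_radius_frac=0.3,
        shape_irregularity=0.0,
        noise_sd=0.0,
        bias_strength=0.0,
        contrast_gradient=0.0,
    )


@pytest.fixture
def phantom_case(small_domain):
    return generate_case(small_domain, "case-0", "pat-0", seed=11)


def random_binary_mask(rng, shape, p=0.3, spacing=(1.0, 1.0, 1.0)):
    data = (rng.random(shape) < p).astype(np.float32)
    return SegmentationMask(data, spacing)


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=np.float32), spacing)
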