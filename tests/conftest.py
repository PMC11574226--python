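import numpy as np
import pytest

from mammoblur.pipeline import PipelineConfig
from mammoblur.preprocess import PreprocessConfig
from mammoblur.synthetic import BlurRegion, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def sharp_phantom():
    """One 1,200-px phantom without blur (session-cached: generation is the
    slow part of many tests)."""
    return generate_phantom(PhantomConfig(image_px=1200, seed=11))


@pytest.fixture(scope="session")
def blurred_phantom():
    """Phantom with a single lattice-aligned blurred rectangle (PSF 8 px)."""
    poly = np.array([[200.0, 400.0], [800.0, 400.0], [800.0, 800.0], [200.0, 800.0]])
    cfg = PhantomConfig(
        image_px=1200, seed=11, blur_regions=[BlurRegion(poly, psf_length_px=8.0, psf_angle_deg=30.0)]
    )
    return generate_phantom(cfg)


@pytest.fixture()
def test_scale_config():
    """Pipeline config pinned to the 1,200-px test canvas."""
    cfg = PipelineConfig()
    cfg.preprocessing = PreprocessConfig(canvas_size_px=1200)
    return cfg
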