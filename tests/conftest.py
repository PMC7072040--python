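import numpy as np
import pytest

from dxaspine import PhantomSpec, generate_phantom, segment_body, standardize_height
from dxaspine.config import PipelineConfig


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def phantom15(cfg):
    """Seeded 15-degree single-C phantom with default noise, native resolution."""
    spec = PhantomSpec(curve_angle_deg=15, curve_pattern="single_C", noise_sigma=0.02, seed=3)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def seg15(cfg, phantom15):
    img, _ = phantom15
    return segment_body(img, cfg)


@pytest.fixture(scope="session")
def phantom20_clean(cfg):
    """Noiseless, untilted 20-degree phantom."""
    spec = PhantomSpec(curve_angle_deg=20, curve_pattern="single_C", noise_sigma=0.0, seed=1)
    return generate_phantom(spec)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
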