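import numpy as np
import pytest

from evtem.detect import DetectionConfig
from evtem.synthetic import DiameterDistribution, SceneParams, simulate_scene


def disc_mask(radius: int) -> np.ndarray:
    """Rasterized disc as a boolean raster (pixel centers within radius)."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def ellipse_mask(a: int, b: int) -> np.ndarray:
    """Axis-aligned rasterized ellipse with semi-axes a (x) and b (y)."""
    yy, xx = np.mgrid[-b : b + 1, -a : a + 1]
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


@pytest.fixture
def default_config() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def make_scene():
    """Factory for seeded synthetic scenes with overridable parameters."""

    def _make(seed: int = 0, **kw):
        return simulate_scene(SceneParams(seed=seed, **kw))

    return _make


@pytest.fixture
def clean_scene(make_scene):
    """A noise-free circular-particle scene with known normal diameters."""
    return make_scene(
        seed=42,
        noise_sd=0.0,
        aspect_range=(1.0, 1.0),
        cup_probability=0.0,
        diameters=DiameterDistribution("normal", 36.0, 10.0),
    )
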