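import numpy as np
import pytest

from bovimetry.phantom import CowPhantom
from bovimetry.sensor import SensorModel


@pytest.fixture(scope="session")
def phantom():
    """Default young-calf phantom with analytic ground truth."""
    return CowPhantom()


@pytest.fixture(scope="session")
def sensor_1m():
    """Table-performance sensor at 1 m working distance."""
    return SensorModel.at_distance(1000.0)


@pytest.fixture(scope="session")
def sensor_1m_clean(sensor_1m):
    """Same sensor with noise, quantization and distortion off."""
    return sensor_1m.noiseless()


@pytest.fixture(scope="session")
def rendered_views(phantom, sensor_1m_clean):
    """Noiseless canonical views of the default phantom (cached per session)."""
    from bovimetry.render import render_depth

    return {
        view: render_depth(phantom, view, sensor_1m_clean, seed=0)
        for view in ("top", "left", "right", "front")
    }


def sphere_cloud(radius=100.0, n=500, center=(0.0, 0.0, 0.0), seed=0,
                 noise_sd=0.0):
    """Uniform points on a sphere, optional radial Gaussian noise."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius + (rng.normal(0.0, noise_sd, n) if noise_sd else np.zeros(n))
    return v * r[:, None] + np.asarray(center)
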