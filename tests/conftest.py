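import numpy as np
import pytest

from nightgrape import (
    ChannelImage,
    PipelineConfig,
    SceneParams,
    extract_red,
    generate_scene,
    rotate_channel,
    standardize,
)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def noise_free_scene():
    """Default centered cluster rendered without noise, with its truth."""
    params = SceneParams(seed=3, noise_sd=0.0)
    return generate_scene(params)


@pytest.fixture
def rotated_channel(noise_free_scene):
    """Rotated R component of the noise-free scene at working resolution."""
    img, _ = noise_free_scene
    return rotate_channel(extract_red(standardize(img)))


def disk_channel(shape=(60, 60), center=(30, 30), radius=15, lo=40, hi=215):
    """Bright disk on dark ground, the minimal two-region fixture."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, lo, dtype=np.uint8)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 < radius**2] = hi
    truth = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 < radius**2
    return ChannelImage(img), truth
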