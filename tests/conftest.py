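import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_frame(gray_image: np.ndarray) -> np.ndarray:
    """Lift a 2-D gray image to an RGB frame with equal channels."""
    gray_image = np.asarray(gray_image, dtype=float)
    return np.stack([gray_image] * 3, axis=-1)


def disk_frame(size: int = 64, radius: int = 20, color=(0.8, 0.8, 0.8)) -> np.ndarray:
    """Bright centered disk on black background."""
    frame = np.zeros((size, size, 3))
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    frame[mask] = color
    return frame
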