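"""The bespoke filter bank.

Four image operators drive the per-frame descriptors: true 2-D convolution,
Sobel gradient magnitude, a narrow contrast window around the image mean,
and a hand-tuned 3x3 crack-detection kernel.  All convolutions use
reflect-padding and keep the input size.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d as _convolve2d_full

from .preprocess import binarize

__all__ = [
    "SOBEL_GX",
    "SOBEL_GY",
    "CRACK_KERNEL",
    "CRACK_THRESHOLD",
    "kernel_from_letters",
    "convolve2d",
    "sobel_magnitude",
    "adjust_contrast_window",
    "modified_sobel",
    "crack_filter_response",
    "crack_response",
]

#: Horizontal-gradient Sobel core; the vertical core is its 90-degree rotation.
SOBEL_GX = np.array(
    [
        [+1.0, 0.0, -1.0],
        [+2.0, 0.0, -2.0],
        [+1.0, 0.0, -1.0],
    ]
)
SOBEL_GY = np.rot90(SOBEL_GX)

#: Row-major crack kernel A..I.  Center weight dominates so flat tissue maps
#: to a positive response while dark crack pixels fall below the threshold.
CRACK_KERNEL = np.array(
    [
        [-2.3, -1.0, -0.3],
        [-1.4, 7.8, -1.4],
        [-0.3, -1.0, 0.0],
    ]
)

#: Response threshold separating tissue (>= 5) from cracks, on 0-255 gray.
CRACK_THRESHOLD = 5.0


def kernel_from_letters(values: dict[str, float]) -> np.ndarray:
    """Build a 3x3 kernel from nine named coefficients A..I (row-major)."""
    letters = "ABCDEFGHI"
    missing = [x for x in letters if x not in values]
    if missing:
        raise ValueError(f"kernel spec missing coefficients: {missing}")
    return np.array([float(values[x]) for x in letters]).reshape(3, 3)


def _check_kernel(kernel: np.ndarray) -> np.ndarray:
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape != (3, 3) or not np.isfinite(kernel).all():
        raise ValueError("kernel must be a finite 3x3 array")
    return kernel


def convolve2d(gray: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size true 2-D convolution (kernel flipped) with reflected edges."""
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("input must be a 2-D array of at least 3x3")
    kernel = _check_kernel(kernel)
    return _convolve2d_full(gray, kernel, mode="same", boundary="symm")


def sobel_magnitude(gray: np.ndarray) -> np.ndarray:
    """Pixel-wise sqrt(Gx^2 + Gy^2) of the two Sobel convolutions."""
    gx = convolve2d(gray, SOBEL_GX)
    gy = convolve2d(gray, SOBEL_GY)
    return np.hypot(gx, gy)


def adjust_contrast_window(gray: np.ndarray, k: float = 0.2) -> np.ndarray:
    """Rescale the window [mean - k*std, mean + k*std] to [0, 1], clipping.

    A constant image (zero standard deviation) maps to uniform mid-gray.
    """
    gray = np.asarray(gray, dtype=float)
    m = gray.mean()
    s = gray.std()
    if s == 0.0:
        return np.full(gray.shape, 0.5)
    lo = m - k * s
    return np.clip((gray - lo) / (2.0 * k * s), 0.0, 1.0)


def modified_sobel(gray: np.ndarray, k: float = 0.2) -> np.ndarray:
    """Contrast-windowed Sobel edge mask.

    Pipeline: contrast window -> Sobel magnitude -> normalize by the maximum
    -> Otsu binarization.  Marks fold/edge pixels; a constant input yields an
    all-zero mask.
    """
    mag = sobel_magnitude(adjust_contrast_window(gray, k=k))
    peak = mag.max()
    if peak == 0.0:
        return np.zeros(gray.shape, dtype=np.uint8)
    return binarize(mag / peak, "auto")


def crack_filter_response(gray: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Raw crack-kernel response on the 0-255 gray scale (may be negative)."""
    if kernel is None:
        kernel = CRACK_KERNEL
    gray = np.asarray(gray, dtype=float)
    if gray.max() <= 1.0:
        gray = gray * 255.0
    return convolve2d(gray, kernel)


def crack_response(
    gray: np.ndarray,
    kernel: np.ndarray | None = None,
    threshold: float = CRACK_THRESHOLD,
) -> np.ndarray:
    """Binary tissue mask from the crack kernel.

    1 marks tissue (response >= threshold), 0 marks cracks, so *low* pixel
    sums over this mask indicate heavily cracked mucosa.  Gray input in
    [0, 1] is lifted to 0-255 because the threshold is on the 8-bit scale.
    """
    return (crack_filter_response(gray, kernel) >= threshold).astype(np.uint8)
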