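"""Frame cleanup: overlay-text removal and black-border cropping.

A *frame* is an ``(H, W, 3)`` float array with channel values in ``[0, 1]``;
a *gray frame* is the ``(H, W)`` luminance raster derived from it.  Both of
the public cleanup operations are idempotent so they can be re-applied to
already-clean material without harm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "LUMA_WEIGHTS",
    "LabeledRegion",
    "validate_frame",
    "to_grayscale",
    "binarize",
    "label_regions",
    "remove_overlay_text",
    "crop_black_border",
]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class LabeledRegion:
    """One 8-connected component of a binary mask."""

    coords: np.ndarray  # (N, 2) row/col pixel coordinates
    area: int
    centroid: tuple[float, float]  # (row, col)


def validate_frame(frame: np.ndarray) -> np.ndarray:
    """Check frame shape, dtype domain and minimum size; return as float64."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"frame must be (H, W, 3), got shape {frame.shape}")
    if frame.shape[0] < 3 or frame.shape[1] < 3:
        raise ValueError("frame must be at least 3x3 pixels")
    if frame.size == 0:
        raise ValueError("frame is empty")
    if frame.min() < 0.0 or frame.max() > 1.0:
        raise ValueError("frame channel values must lie in [0, 1]")
    return frame


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Weighted-luminance grayscale conversion of an RGB frame."""
    frame = validate_frame(frame)
    return frame @ LUMA_WEIGHTS


def binarize(gray: np.ndarray, threshold: float | str = "auto") -> np.ndarray:
    """Threshold a gray frame to a {0, 1} uint8 mask.

    ``threshold="auto"`` picks Otsu's histogram threshold; a constant image
    (no Otsu threshold definable) maps to an all-zero mask.  Pixels strictly
    above the threshold become 1.
    """
    gray = np.asarray(gray, dtype=float)
    if threshold == "auto":
        if np.ptp(gray) == 0.0:
            return np.zeros(gray.shape, dtype=np.uint8)
        threshold = threshold_otsu(gray)
    else:
        threshold = float(threshold)
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return (gray > threshold).astype(np.uint8)


def label_regions(mask: np.ndarray) -> list[LabeledRegion]:
    """8-connected components of the 1-pixels of a binary mask."""
    mask = np.asarray(mask)
    labeled = measure.label(mask, connectivity=2)
    regions = []
    for props in measure.regionprops(labeled):
        regions.append(
            LabeledRegion(
                coords=props.coords,
                area=int(props.area),
                centroid=(float(props.centroid[0]), float(props.centroid[1])),
            )
        )
    return regions


def remove_overlay_text(frame: np.ndarray, border_fraction: float = 0.2) -> np.ndarray:
    """Erase bright regions whose centroids sit in the outer border band.

    The frame is grayscaled and auto-binarized; every connected bright
    region whose centroid lies within ``border_fraction`` of the frame
    height from the top/bottom edge or of the frame width from the
    left/right edge is zeroed in all channels.  Device overlay text sits in
    the corners of capsule frames and is wiped by this rule, while the
    central mucosa field is untouched.
    """
    if not 0.0 < border_fraction < 0.5:
        raise ValueError(f"border_fraction must be in (0, 0.5), got {border_fraction}")
    frame = validate_frame(frame)
    h, w = frame.shape[:2]
    mask = binarize(to_grayscale(frame), "auto")
    out = frame.copy()
    for region in label_regions(mask):
        r, c = region.centroid
        in_band = (
            r < border_fraction * h
            or r >= (1.0 - border_fraction) * h
            or c < border_fraction * w
            or c >= (1.0 - border_fraction) * w
        )
        if in_band:
            out[region.coords[:, 0], region.coords[:, 1], :] = 0.0
    return out


def crop_black_border(frame: np.ndarray) -> np.ndarray:
    """Crop to the tight bounding box of non-zero pixels (any channel)."""
    frame = validate_frame(frame)
    nonzero = frame.max(axis=2) > 0.0
    if not nonzero.any():
        raise ValueError("cannot crop an all-zero frame")
    rows = np.flatnonzero(nonzero.any(axis=1))
    cols = np.flatnonzero(nonzero.any(axis=0))
    return frame[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1, :]
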