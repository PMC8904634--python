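"""Per-frame descriptors and per-video summaries.

Ten numbers are computed per frame: grayscale intensity mean and standard
deviation, the three channel means, the pixel sum of the contrast-windowed
Sobel mask, the pixel sum of the crack-kernel tissue mask, the 256-bin
histogram entropy, and the counts of large and small filled edge regions.
A video is summarized by the mean, population standard deviation and
variation (= variance) of each descriptor over its frames.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, transform

from .filters import crack_response, modified_sobel
from .preprocess import to_grayscale, validate_frame

__all__ = [
    "FEATURE_NAMES",
    "SUMMARY_STATS",
    "FrameFeatures",
    "spectral_stats",
    "entropy",
    "mask_pixel_sum",
    "count_regions",
    "frame_features",
    "summarize_video",
    "augment_frame",
    "feature_table",
    "save_feature_table",
    "load_feature_table",
]

FEATURE_NAMES = (
    "intensity_mean",
    "intensity_std",
    "red_mean",
    "green_mean",
    "blue_mean",
    "sobel_sum",
    "crack_sum",
    "entropy",
    "n_large_regions",
    "n_small_regions",
)
SUMMARY_STATS = ("mean", "std", "variation")


@dataclass(frozen=True)
class FrameFeatures:
    intensity_mean: float
    intensity_std: float
    red_mean: float
    green_mean: float
    blue_mean: float
    sobel_sum: int
    crack_sum: int
    entropy: float
    n_large_regions: int
    n_small_regions: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def spectral_stats(frame: np.ndarray) -> tuple[float, float, float, float, float]:
    """Grayscale intensity mean/std plus the three channel means."""
    frame = validate_frame(frame)
    gray = to_grayscale(frame)
    return (
        float(gray.mean()),
        float(gray.std()),
        float(frame[..., 0].mean()),
        float(frame[..., 1].mean()),
        float(frame[..., 2].mean()),
    )


def entropy(gray: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-level gray histogram.

    Values in [0, 1] are quantized to 8-bit levels first; empty bins are
    skipped, so the result lies in [0, 8].
    """
    gray = np.asarray(gray, dtype=float)
    levels = np.clip(np.round(gray * 255.0), 0, 255).astype(np.int64)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())


def mask_pixel_sum(mask: np.ndarray) -> int:
    """Number of 1-pixels in a binary mask."""
    return int(np.asarray(mask).sum())


def count_regions(
    mask: np.ndarray, area_threshold: int = 1000, min_area: int = 10
) -> tuple[int, int]:
    """Count filled connected regions by area.

    Holes are filled before measuring areas.  Large regions have area >=
    ``area_threshold``; small regions have ``min_area`` <= area <
    ``area_threshold`` (anything smaller is treated as noise).
    """
    mask = np.asarray(mask).astype(bool)
    filled = ndimage.binary_fill_holes(mask)
    labeled = measure.label(filled, connectivity=2)
    areas = np.array([p.area for p in measure.regionprops(labeled)], dtype=int)
    n_large = int((areas >= area_threshold).sum())
    n_small = int(((areas >= min_area) & (areas < area_threshold)).sum())
    return n_large, n_small


def frame_features(
    frame: np.ndarray, area_threshold: int = 1000, min_area: int = 10
) -> FrameFeatures:
    """Compute the full 10-field descriptor for one preprocessed frame."""
    frame = validate_frame(frame)
    i_mean, i_std, r_mean, g_mean, b_mean = spectral_stats(frame)
    gray = to_grayscale(frame)
    edge_mask = modified_sobel(gray)
    tissue_mask = crack_response(gray)
    n_large, n_small = count_regions(edge_mask, area_threshold, min_area)
    return FrameFeatures(
        intensity_mean=i_mean,
        intensity_std=i_std,
        red_mean=r_mean,
        green_mean=g_mean,
        blue_mean=b_mean,
        sobel_sum=mask_pixel_sum(edge_mask),
        crack_sum=mask_pixel_sum(tissue_mask),
        entropy=entropy(gray),
        n_large_regions=n_large,
        n_small_regions=n_small,
    )


def summarize_video(frames_features: list[FrameFeatures]) -> dict[str, float]:
    """Per-feature mean, population std and variation (variance) over frames.

    Returns a flat mapping ``{"<feature>_<stat>": value}`` with 30 entries.
    """
    if len(frames_features) < 2:
        raise ValueError("a video summary needs at least 2 frames")
    matrix = np.stack([f.as_array() for f in frames_features])
    summary: dict[str, float] = {}
    for j, name in enumerate(FEATURE_NAMES):
        col = matrix[:, j]
        std = float(col.std())
        summary[f"{name}_mean"] = float(col.mean())
        summary[f"{name}_std"] = std
        summary[f"{name}_variation"] = std**2
    return summary


def augment_frame(
    frame: np.ndarray, op: str, factor: float | None = None
) -> np.ndarray:
    """Geometric augmentation: rotations, mirrors, or central zoom.

    ``zoom`` crops the central 1/factor fraction and rescales back to the
    original size; the factor must lie in (1, 2].  Rotations of non-square
    frames return the rotated (W, H, 3) raster.
    """
    frame = validate_frame(frame)
    if op == "rotate90":
        return np.rot90(frame, 1)
    if op == "rotate180":
        return np.rot90(frame, 2)
    if op == "rotate270":
        return np.rot90(frame, 3)
    if op == "mirror_h":
        return frame[:, ::-1, :]
    if op == "mirror_v":
        return frame[::-1, :, :]
    if op == "zoom":
        if factor is None or factor == 1.0:
            return frame
        if not 1.0 < factor <= 2.0:
            raise ValueError(f"zoom factor must be in (1, 2], got {factor}")
        h, w = frame.shape[:2]
        ch, cw = max(3, int(round(h / factor))), max(3, int(round(w / factor)))
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        crop = frame[r0 : r0 + ch, c0 : c0 + cw, :]
        out = transform.resize(crop, (h, w, 3), order=1, anti_aliasing=True)
        return np.clip(out, 0.0, 1.0)
    raise ValueError(f"unknown augmentation op: {op!r}")


def feature_table(
    video_ids: list[str], labels: list[str], summaries: list[dict[str, float]]
) -> pd.DataFrame:
    """Assemble per-video summaries into the canonical 32-column table."""
    columns = [f"{n}_{s}" for n in FEATURE_NAMES for s in SUMMARY_STATS]
    rows = [[summary[c] for c in columns] for summary in summaries]
    df = pd.DataFrame(rows, columns=columns)
    df.insert(0, "label", labels)
    df.insert(0, "video_id", video_ids)
    return df


def save_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
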