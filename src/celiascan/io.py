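"""PNG/JPEG frame I/O; a video is a directory of lexicographically ordered frames."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["load_frame", "save_frame", "load_video", "save_video"]

_FRAME_SUFFIXES = {".png", ".jpg", ".jpeg"}


def load_frame(path) -> np.ndarray:
    """Read an 8-bit RGB image into a [0, 1] float frame."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[2] == 4:  # drop alpha
        raw = raw[..., :3]
    return raw.astype(float) / 255.0


def save_frame(path, frame: np.ndarray) -> None:
    """Write a [0, 1] float frame as 8-bit PNG/JPEG."""
    data = np.clip(np.asarray(frame) * 255.0, 0, 255).round().astype(np.uint8)
    iio.imwrite(path, data)


def frame_paths(video_dir) -> list[Path]:
    return sorted(
        p for p in Path(video_dir).iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )


def load_video(video_dir) -> list[np.ndarray]:
    return [load_frame(p) for p in frame_paths(video_dir)]


def save_video(video_dir, frames: list[np.ndarray]) -> None:
    video_dir = Path(video_dir)
    video_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        save_frame(video_dir / f"frame_{i:04d}.png", frame)
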