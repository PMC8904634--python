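"""Seeded synthetic capsule-endoscopy-like frames and videos.

Each frame is a roughly circular mucosa field on a black background with
class-conditioned base color, Gaussian texture noise, bright fold ridges,
dark crack polylines and an optional bitmap timestamp overlay in a corner.
Healthy and celiac default phenotypes differ in color (healthy redder),
fold count (healthy more) and crack density (celiac more), mirroring the
contrasts the feature pipeline is built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import draw

__all__ = [
    "PhenotypeParams",
    "SyntheticVideoSpec",
    "HEALTHY_PHENOTYPE",
    "CELIAC_PHENOTYPE",
    "default_phenotype",
    "generate_frame",
    "generate_video",
    "generate_dataset",
]


@dataclass(frozen=True)
class PhenotypeParams:
    label: str
    base_rgb_mean: tuple[float, float, float]
    base_rgb_noise_std: float = 0.02
    n_folds: int = 4
    fold_brightness: float = 0.15
    crack_density: float = 2.0
    crack_darkness: float = 0.1
    field_radius_fraction: float = 0.8
    overlay_text: bool = True
    frame_size: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if not all(0.0 <= c <= 1.0 for c in self.base_rgb_mean):
            raise ValueError("base_rgb_mean components must lie in [0, 1]")
        if self.crack_density < 0:
            raise ValueError("crack_density must be >= 0")
        if not 0.0 < self.field_radius_fraction <= 1.0:
            raise ValueError("field_radius_fraction must lie in (0, 1]")


#: Class defaults: channel means follow the measured per-class spectra
#: (healthy mucosa is redder); celiac mucosa carries few folds, many cracks.
HEALTHY_PHENOTYPE = PhenotypeParams(
    label="healthy",
    base_rgb_mean=(0.4265, 0.2914, 0.1551),
    base_rgb_noise_std=0.02,
    n_folds=6,
    crack_density=1.0,
)
CELIAC_PHENOTYPE = PhenotypeParams(
    label="celiac",
    base_rgb_mean=(0.3340, 0.2749, 0.1654),
    base_rgb_noise_std=0.03,
    n_folds=2,
    crack_density=12.0,
)


def default_phenotype(label: str) -> PhenotypeParams:
    if label == "healthy":
        return HEALTHY_PHENOTYPE
    if label == "celiac":
        return CELIAC_PHENOTYPE
    raise ValueError(f"unknown label: {label!r}")


@dataclass(frozen=True)
class SyntheticVideoSpec:
    phenotype: PhenotypeParams
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a video needs at least 2 frames")


# 5x7 bitmap glyphs for the timestamp overlay (no font dependency).
_GLYPHS = {
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    ":": ("00000", "00100", "00000", "00000", "00100", "00000", "00000"),
}


def _draw_text(frame: np.ndarray, text: str, top: int, left: int) -> None:
    col = left
    for ch in text:
        glyph = _GLYPHS.get(ch)
        if glyph is None:
            col += 6
            continue
        for r, row in enumerate(glyph):
            for c, bit in enumerate(row):
                if bit == "1" and top + r < frame.shape[0] and col + c < frame.shape[1]:
                    frame[top + r, col + c, :] = 1.0
        col += 6


def _random_point_in_disk(
    rng: np.random.Generator, center: tuple[float, float], radius: float
) -> tuple[float, float]:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    rho = radius * np.sqrt(rng.uniform(0.0, 1.0))
    return center[0] + rho * np.sin(theta), center[1] + rho * np.cos(theta)


def _bezier_points(p0, p1, p2, n: int = 80) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * np.array(p0) + 2 * (1 - t) * t * np.array(p1) + t**2 * np.array(p2)
    return pts


def _stamp_curve(
    canvas_mask: np.ndarray, pts: np.ndarray, width: int, field: np.ndarray
) -> np.ndarray:
    """Rasterize a polyline of the given width, clipped to the mucosa field."""
    h, w = canvas_mask.shape
    hit = np.zeros((h, w), dtype=bool)
    rr_all, cc_all = [], []
    ipts = np.round(pts).astype(int)
    for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = draw.line(r0, c0, r1, c1)
        rr_all.append(rr)
        cc_all.append(cc)
    rr = np.concatenate(rr_all)
    cc = np.concatenate(cc_all)
    for dr in range(width):
        for dc in range(width):
            r = np.clip(rr + dr, 0, h - 1)
            c = np.clip(cc + dc, 0, w - 1)
            hit[r, c] = True
    return hit & field


def generate_frame(p: PhenotypeParams, seed) -> np.ndarray:
    """Render one synthetic frame; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    h, w = p.frame_size
    frame = np.zeros((h, w, 3), dtype=float)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    radius = p.field_radius_fraction * min(h, w) / 2.0

    rr, cc = draw.disk(center, radius, shape=(h, w))
    field = np.zeros((h, w), dtype=bool)
    field[rr, cc] = True
    base = np.array(p.base_rgb_mean)
    frame[field] = base
    if p.base_rgb_noise_std > 0:
        # spatially correlated texture noise: white noise smoothed and
        # rescaled, so high-frequency kernels see mucosa, not salt-and-pepper
        noise = rng.normal(0.0, 1.0, size=(h, w, 3))
        noise = ndimage.gaussian_filter(noise, sigma=(2.0, 2.0, 0.0))
        noise *= p.base_rgb_noise_std / noise.std()
        frame[field] = frame[field] + noise[field]

    # fold ridges: a bright crest with an adjacent dark groove, so the fold
    # presents a strong local transition to gradient filters
    for _ in range(p.n_folds):
        p0 = _random_point_in_disk(rng, center, radius * 0.9)
        p1 = _random_point_in_disk(rng, center, radius * 0.7)
        p2 = _random_point_in_disk(rng, center, radius * 0.9)
        pts = _bezier_points(p0, p1, p2)
        crest = _stamp_curve(field, pts, width=2, field=field)
        groove = _stamp_curve(field, pts + np.array([3.0, 3.0]), width=2, field=field)
        groove &= ~crest
        frame[crest] = frame[crest] + p.fold_brightness
        frame[groove] = frame[groove] - p.fold_brightness

    # dark crack polylines; count is Poisson in the density
    n_cracks = int(rng.poisson(p.crack_density))
    for _ in range(n_cracks):
        start = _random_point_in_disk(rng, center, radius * 0.85)
        pts = [np.array(start)]
        angle = rng.uniform(0.0, 2.0 * np.pi)
        for _ in range(rng.integers(3, 7)):
            angle += rng.normal(0.0, 0.6)
            step = rng.uniform(4.0, 10.0)
            pts.append(pts[-1] + step * np.array([np.sin(angle), np.cos(angle)]))
        width = int(rng.integers(1, 3))
        hit = _stamp_curve(field, np.array(pts), width=width, field=field)
        frame[hit] = base * p.crack_darkness

    frame = np.clip(frame, 0.0, 1.0)
    frame[~field] = 0.0

    if p.overlay_text:
        _draw_text(frame, "12:34:56", top=1, left=1)
    return frame


def generate_video(spec: SyntheticVideoSpec) -> list[np.ndarray]:
    """Render ``n_frames`` frames with per-frame derived seeds."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_frames)
    return [generate_frame(spec.phenotype, child) for child in children]


def generate_dataset(
    n_healthy: int,
    n_celiac: int,
    seed: int = 0,
    n_frames: int = 100,
    frame_size: tuple[int, int] | None = None,
) -> tuple[list[list[np.ndarray]], list[str]]:
    """Labeled synthetic videos at the default class phenotypes."""
    if n_healthy < 1 or n_celiac < 1:
        raise ValueError("counts must be >= 1")
    labels = ["healthy"] * n_healthy + ["celiac"] * n_celiac
    ss = np.random.SeedSequence(seed)
    videos = []
    for label, child in zip(labels, ss.spawn(len(labels))):
        phenotype = default_phenotype(label)
        if frame_size is not None:
            phenotype = replace(phenotype, frame_size=frame_size)
        video_seed = int(child.generate_state(1)[0])
        videos.append(
            generate_video(SyntheticVideoSpec(phenotype, n_frames=n_frames, seed=video_seed))
        )
    return videos, labels
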