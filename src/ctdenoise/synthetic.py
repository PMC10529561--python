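"""Synthetic phantoms and low-dose degradation.

Real low-dose CT pairs come from clinical archives; for testing the
pipeline end to end without any download this module generates
piecewise-constant phantoms that mimic the gross structure of abdominal
CT slices — overlapping elliptical "organs" at a handful of tissue-like
intensity levels with sharp boundaries, plus a few small low-contrast
"lesion" discs — and degrades them with additive i.i.d. Gaussian noise
whose standard deviation is quoted on the 8-bit scale (sigma8/255
internally), the usual convention for denoising benchmarks with sigma
values between 5 and 30.

Noisy images are deliberately NOT clipped to [0, 1]: clipping would
skew the noise statistics the denoiser sees.  Clipping happens only on
export to integer pixel formats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .image import GrayImage

__all__ = ["PhantomSpec", "NoiseSpec", "generate_phantom", "add_gaussian_noise"]

#: tissue-like gray levels (background, fluid, soft tissue, organs, bone-ish)
DEFAULT_LEVELS = (0.10, 0.25, 0.40, 0.55, 0.70, 0.85)


@dataclass(frozen=True)
class PhantomSpec:
    """Piecewise-constant phantom description; identical spec + seed => identical image."""

    height: int = 128
    width: int = 128
    n_shapes: int = 6
    intensity_levels: tuple[float, ...] = DEFAULT_LEVELS
    lesion_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ParameterError("phantom dimensions must be positive")
        if self.n_shapes < 0 or self.lesion_count < 0:
            raise ParameterError("n_shapes and lesion_count must be >= 0")
        if len(self.intensity_levels) == 0:
            raise ParameterError("intensity_levels must not be empty")
        for lv in self.intensity_levels:
            if not (0.0 <= lv <= 1.0):
                raise ParameterError(f"intensity level {lv} outside [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise, std quoted on the 8-bit scale (internal sigma8/255)."""

    sigma8: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma8 > 0):
            raise ParameterError(f"sigma8 must be > 0, got {self.sigma8}")

    @property
    def sigma(self) -> float:
        return self.sigma8 / 255.0


def generate_phantom(spec: PhantomSpec) -> GrayImage:
    """Render the phantom: background + ellipses + low-contrast lesion discs.

    Ellipse fills are drawn exactly from ``intensity_levels`` (no blending),
    so a lesion-free phantom's histogram contains only the specified levels.
    Lesions are small discs offset by +/-0.06 from the underlying tissue.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    levels = np.asarray(spec.intensity_levels, dtype=np.float64)
    img = np.full((H, W), levels[0])
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    for _ in range(spec.n_shapes):
        cy = rng.uniform(0.2, 0.8) * H
        cx = rng.uniform(0.2, 0.8) * W
        ay = rng.uniform(0.10, 0.32) * H
        ax = rng.uniform(0.10, 0.32) * W
        theta = rng.uniform(0.0, np.pi)
        level = levels[rng.integers(len(levels))]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        img[(u / ax) ** 2 + (v / ay) ** 2 <= 1.0] = level

    for _ in range(spec.lesion_count):
        cy = rng.uniform(0.15, 0.85) * H
        cx = rng.uniform(0.15, 0.85) * W
        r = rng.uniform(2.0, 5.0)
        delta = rng.choice((-0.06, 0.06))
        base = img[min(int(cy), H - 1), min(int(cx), W - 1)]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[disc] = np.clip(base + delta, 0.0, 1.0)

    return img


def add_gaussian_noise(img: GrayImage, noise: NoiseSpec) -> GrayImage:
    """Add seeded i.i.d. Gaussian noise of std ``sigma8/255``; no clipping."""
    rng = np.random.default_rng(noise.seed)
    img = np.asarray(img, dtype=np.float64)
    return img + rng.normal(0.0, noise.sigma, size=img.shape)
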