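"""Image-quality metrics and intensity line profiles.

PSNR and RMSE are implemented directly (they are one-liners); SSIM wraps
the reference implementation in scikit-image with the standard constants
(11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03) on a dynamic range
of 1.0.  Line profiles sample pixel values along the Bresenham traversal
of a segment, the usual way edge sharpness is inspected in CT denoising
work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as bresenham_line
from skimage.metrics import structural_similarity

from .errors import ContractError, ParameterError
from .image import GrayImage, as_gray_image, check_same_shape

__all__ = [
    "MetricReport",
    "LineProfile",
    "rmse",
    "psnr",
    "ssim",
    "compute_metrics",
    "line_profile",
    "profile_overlap",
]


@dataclass(frozen=True)
class MetricReport:
    """PSNR (dB), RMSE (intensity units) and SSIM for one image pair."""

    psnr: float
    rmse: float
    ssim: float

    def to_dict(self) -> dict:
        return {"psnr": self.psnr, "rmse": self.rmse, "ssim": self.ssim}


@dataclass(frozen=True)
class LineProfile:
    """Intensities sampled along the Bresenham traversal of a segment."""

    positions: np.ndarray  # 0..n-1 sample indices along the segment
    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray


def rmse(ref: GrayImage, test: GrayImage) -> float:
    """Root-mean-square error ``sqrt(mean((ref - test)**2))``."""
    ref = as_gray_image(ref)
    test = as_gray_image(test)
    check_same_shape(ref, test)
    return float(np.sqrt(np.mean((ref - test) ** 2)))


def psnr(ref: GrayImage, test: GrayImage, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``20*log10(peak / rmse)`` in dB.

    Returns ``math.inf`` for identical images.
    """
    if not (peak > 0):
        raise ParameterError(f"peak must be > 0, got {peak}")
    err = rmse(ref, test)
    if err == 0.0:
        return math.inf
    return float(20.0 * np.log10(peak / err))


def ssim(ref: GrayImage, test: GrayImage) -> float:
    """Mean structural similarity index on a dynamic range of 1.0."""
    ref = as_gray_image(ref)
    test = as_gray_image(test)
    check_same_shape(ref, test)
    if min(ref.shape) < 11:
        raise ParameterError(f"image smaller than the 11x11 SSIM window: {ref.shape}")
    return float(
        structural_similarity(
            ref,
            test,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
    )


def compute_metrics(ref: GrayImage, test: GrayImage, peak: float = 1.0) -> MetricReport:
    return MetricReport(psnr=psnr(ref, test, peak), rmse=rmse(ref, test), ssim=ssim(ref, test))


def line_profile(img: GrayImage, p0: tuple[int, int], p1: tuple[int, int]) -> LineProfile:
    """Pixel values along the discrete segment from ``p0`` to ``p1`` (inclusive)."""
    img = as_gray_image(img)
    H, W = img.shape
    for r, c in (p0, p1):
        if not (0 <= r < H and 0 <= c < W):
            raise ContractError(f"endpoint {(r, c)} outside image of shape {img.shape}")
    rr, cc = bresenham_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    return LineProfile(
        positions=np.arange(len(rr)), rows=rr, cols=cc, values=img[rr, cc]
    )


def profile_overlap(a: LineProfile, b: LineProfile) -> float:
    """Mean absolute difference between two profiles of the same segment (0 = overlap)."""
    if len(a.values) != len(b.values):
        raise ContractError("profiles have different lengths")
    return float(np.mean(np.abs(a.values - b.values)))
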