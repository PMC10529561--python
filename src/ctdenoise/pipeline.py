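"""The full two-stage denoising pipeline and its tiled evaluation.

Order of stages (the lowpass operates on the NLM output ``u``, not on
the raw noisy image): prefix-sum NLM -> Gaussian lowpass base ->
signed residual -> positive/negative split -> region selection M on
each half -> recomposition ``I_out = I_o + c*(M+ - M-)``.

Tiling: NLM and the lowpass are strictly local (receptive fields
``K + P`` and ``ceil(3*sigma)`` pixels), so with a sufficient halo each
tile reproduces the untiled result exactly and tiles could be processed
in parallel.  Geodesic reconstruction is NOT local — a marker can
propagate across the whole image — so the morphological stage always
runs globally on the assembled residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .image import GrayImage, as_gray_image
from .morphology import (
    compose_output,
    lowpass,
    morph_select,
    residual,
    split_residual,
)
from .nlm import _nlm_from_extended, extend_boundary, nlm_fast
from .params import NLMParams, PipelineConfig

__all__ = ["DenoiseResult", "denoise", "denoise_tiled", "nlm_tiled", "lowpass_tiled"]


@dataclass(frozen=True)
class DenoiseResult:
    """All intermediates of one pipeline run, retained for inspection."""

    u: GrayImage          # NLM output
    Io: GrayImage         # lowpass base
    res: GrayImage        # signed residual u - Io
    pos: GrayImage        # non-negative residual halves
    neg: GrayImage
    m_pos: GrayImage      # morphologically selected halves M(I_res+/-)
    m_neg: GrayImage
    out: GrayImage        # I_o + c*(m_pos - m_neg), unclipped


def _morph_stage(u: GrayImage, cfg: PipelineConfig) -> DenoiseResult:
    mp = cfg.morph
    Io = lowpass(u, mp.lowpass_sigma)
    res = residual(u, Io)
    pair = split_residual(res)
    m_pos = morph_select(pair.pos, mp.t, mp.s_size, mp.connectivity)
    m_neg = morph_select(pair.neg, mp.t, mp.s_size, mp.connectivity)
    out = compose_output(Io, m_pos, m_neg, mp.c)
    return DenoiseResult(
        u=u, Io=Io, res=res, pos=pair.pos, neg=pair.neg, m_pos=m_pos, m_neg=m_neg, out=out
    )


def denoise(img: GrayImage, cfg: PipelineConfig | None = None) -> DenoiseResult:
    """Run the full pipeline (untiled).  Deterministic: no randomness anywhere."""
    cfg = cfg or PipelineConfig()
    img = as_gray_image(img)
    u = nlm_fast(img, cfg.nlm)
    return _morph_stage(u, cfg)


def _tile_ranges(n: int, size: int):
    for start in range(0, n, size):
        yield start, min(start + size, n)


def nlm_tiled(img: GrayImage, params: NLMParams, tile: int, halo: int | None = None) -> GrayImage:
    """NLM stage evaluated tile by tile with a halo of surrounding context.

    ``halo`` must be at least ``K + P`` (the NLM receptive field); the result
    then matches `nlm_fast` to floating rounding.  The image is extended once
    with the configured boundary mode; each tile reads only its own window.
    """
    img = as_gray_image(img)
    if tile < 1:
        raise ParameterError(f"tile size must be >= 1, got {tile}")
    required = params.margin
    if halo is None:
        halo = required
    if halo < required:
        raise ParameterError(f"halo {halo} insufficient for NLM receptive field {required}")
    H, W = img.shape
    E = extend_boundary(img, halo, params.boundary)
    out = np.empty_like(img)
    for r0, r1 in _tile_ranges(H, tile):
        for c0, c1 in _tile_ranges(W, tile):
            window = E[r0 : r1 + 2 * halo, c0 : c1 + 2 * halo]
            out[r0:r1, c0:c1] = _nlm_from_extended(window, r1 - r0, c1 - c0, halo, params)
    return out


def lowpass_tiled(u: GrayImage, sigma: float, tile: int, halo: int) -> GrayImage:
    """Gaussian lowpass evaluated per tile; exact when ``halo >= ceil(3*sigma)``."""
    u = as_gray_image(u)
    radius = int(np.ceil(3 * sigma))
    if halo < radius:
        raise ParameterError(f"halo {halo} insufficient for lowpass radius {radius}")
    H, W = u.shape
    out = np.empty_like(u)
    for r0, r1 in _tile_ranges(H, tile):
        for c0, c1 in _tile_ranges(W, tile):
            # clip the halo window at the image border so the tile sees the
            # same (reflected) boundary as the untiled filter
            wr0, wr1 = max(0, r0 - halo), min(H, r1 + halo)
            wc0, wc1 = max(0, c0 - halo), min(W, c1 + halo)
            filtered = lowpass(u[wr0:wr1, wc0:wc1], sigma)
            out[r0:r1, c0:c1] = filtered[r0 - wr0 : r1 - wr0, c0 - wc0 : c1 - wc0]
    return out


def denoise_tiled(img: GrayImage, cfg: PipelineConfig) -> DenoiseResult:
    """Full pipeline with the linear stages (NLM + lowpass) evaluated per tile.

    Requires ``cfg.tile``; its halo must cover ``K + P + ceil(3*lowpass_sigma)``
    (defaulted when unset).  The morphological stage runs globally.
    """
    if cfg.tile is None:
        raise ParameterError("denoise_tiled requires cfg.tile")
    img = as_gray_image(img)
    required = cfg.min_halo()
    halo = cfg.tile.halo if cfg.tile.halo is not None else required
    if halo < required:
        raise ParameterError(
            f"halo {halo} insufficient: NLM + lowpass receptive field is {required}"
        )
    u = nlm_tiled(img, cfg.nlm, cfg.tile.size, halo)
    mp = cfg.morph
    Io = lowpass_tiled(u, mp.lowpass_sigma, cfg.tile.size, halo)
    res = residual(u, Io)
    pair = split_residual(res)
    m_pos = morph_select(pair.pos, mp.t, mp.s_size, mp.connectivity)
    m_neg = morph_select(pair.neg, mp.t, mp.s_size, mp.connectivity)
    out = compose_output(Io, m_pos, m_neg, mp.c)
    return DenoiseResult(
        u=u, Io=Io, res=res, pos=pair.pos, neg=pair.neg, m_pos=m_pos, m_neg=m_neg, out=out
    )
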