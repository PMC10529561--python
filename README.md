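# ctdenoise

Low-dose CT (LDCT) image denoising for image-analysis practitioners who need a
fast, deterministic, fully inspectable classical pipeline: a **prefix-sum
("constructive") non-local means filter** followed by **morphological residual
processing** that restores high-amplitude, sufficiently large edge structures
on top of a lowpass base.

Reducing the X-ray tube current lowers patient dose but floods the
reconstructed slices with noise and streak artifacts. Non-local means (NLM)
suppresses such noise by averaging self-similar patches, but its naive cost
grows with the patch area, and any smoothing blurs the tissue edges and small
lesions a radiologist actually cares about. This package addresses both ends.

## The method

**Stage 1 — NLM with prefix-sum weights.** The estimate at pixel *s* is the
convex combination

    u(s) = 1/Z(s) · Σ_{t ∈ N(s)} w(s,t) · v(t),    Z(s) = Σ_t w(s,t),

over a search window *N(s)* of half-width *K*, with patch-similarity weights

    w(s,t) = g_h( Σ_{δ ∈ Δ} (v(s+δ) − v(t+δ))² ),    g_h(x) = 1 / (1 + x²/h²),

where Δ is the flat (unweighted) patch of half-width *P*. For a fixed
translation *d = t − s* the patch sum is a box sum of the single
squared-difference image `D_d(p) = (v(p) − v(p+d))²`; an integral image
(2-D exclusive prefix sum) of `D_d` yields every box sum from 4 corner reads,
making the per-translation cost independent of the patch size. Iterating over
the (2K+1)² translations reproduces the sliding-window result to floating
rounding; the naive implementation (`nlm_bruteforce`) is kept as a reference
oracle. Disjoint image parts can be filtered independently
(`nlm_tiled`), the basis of parallel evaluation.

**Stage 2 — morphological residual processing.** A Gaussian lowpass base
`I_o = u * L` and the signed residual `Res = u − I_o` are formed; the residual
splits into non-negative halves `I_res± = ½(|Res| ± Res)`. On each half the
operator

    M(I) = R_I( min(I, S_{t,s}(I) | {min I, max I}) )

keeps only residual regions that are high-amplitude (threshold *t*) **and**
large enough (binary area opening, minimum component area *s*), then recovers
their full gray-level shape by geodesic reconstruction `R_I` under *I*. The
output recomposes with a contrast coefficient *c*:

    I_out = I_o + c · (M(I_res+) − M(I_res−)).

Defaults are the published operating point: `P=5, K=3, h=0.15` and
`t=0.15, s=3, c=1.2` on intensities normalized to [0, 1].

## Worked example

```bash
python examples/denoise_phantom.py
```

```
noisy    : PSNR  22.56 dB  SSIM 0.3344  RMSE 0.0745
denoised : PSNR  28.04 dB  SSIM 0.7262  RMSE 0.0396
PSNR gain: +5.48 dB (noise removed while edges are restored from the residual)
```

A 128×128 piecewise-constant abdominal-style phantom is degraded with
additive Gaussian noise of std 20 on the 8-bit scale (σ = 20/255); the
pipeline roughly halves the RMSE and doubles the SSIM at the default
parameters. The other examples show the fast-vs-naive NLM equivalence
(`examples/fast_vs_bruteforce.py`, max deviation ~4e-16), impulse rejection by
the size criterion (`examples/residual_morphology.py`) and intensity line
profiles across edges (`examples/line_profiles.py`).

From Python:

```python
import ctdenoise as ctd

img = ctd.read_image("slice.tif")          # 8/16-bit PNG or TIFF -> [0,1]
result = ctd.denoise(img)                  # published defaults
ctd.write_image(result.out, "denoised.tif")
```

`result` retains every intermediate (`u`, `Io`, `res`, `pos`, `neg`,
`m_pos`, `m_neg`, `out`) for inspection.

Or from the shell:

```bash
ctdenoise simulate --sigma8 20 --seed 7 --out sim/
ctdenoise run --input sim/noisy.tif --output denoised.tif \
    --metrics sim/phantom.tif --profile 64,4,64,123
```

## Scope

Image-domain processing only: no DICOM ingestion, no sinogram/FBP noise
simulation, no FSIM metric, no GPU. The tiling contract stands in for the
SIMD/parallelism claims — correctness is hardware-independent.
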