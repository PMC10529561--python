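# Methods

## Model and assumptions

The pipeline treats a low-dose CT slice as a clean image plus additive,
pixel-wise independent Gaussian noise on intensities normalized to [0, 1].
Two stages run in fixed order:

1. **Non-local means (NLM)** replaces each pixel by a similarity-weighted
   average over a square search window. Patch similarity uses the *flat*
   (unweighted) sum of squared differences over a (2P+1)² patch — not a
   Gaussian-weighted patch — passed through the rational kernel
   `g_h(x) = 1/(1 + x²/h²)`. The self-weight `w(s,s) = g_h(0) = 1` is kept
   as-is, so the normalizer satisfies `Z(s) ≥ 1` and no division guard is
   needed. The output is a convex combination of window values: it can never
   leave the local intensity range, which is what makes the tiling argument
   below exact.
2. **Morphological residual processing** recovers the edges that smoothing
   removed. The Gaussian-lowpass base is deliberately computed from the NLM
   output `u`, not the raw noisy image: `u` is already largely noise-free, so
   its residual `u − I_o` is dominated by genuine structure rather than noise.
   Each non-negative residual half is filtered by `M` (threshold → area
   opening → marker → geodesic reconstruction) and added back with contrast
   `c`.

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| `K` | search-window half-width; (2K+1)² candidate translations | px | 3 |
| `P` | patch half-width; (2P+1)² pixels per similarity patch | px | 5 |
| `h` | filtering strength of `g_h`; weight is ½ when the patch SSD equals `h` | intensity² (SSD scale) | 0.15 |
| `t` | residual amplitude threshold | intensity on [0,1] | 0.15 |
| `s_size` | minimum connected-component area kept by the area opening | px | 3 |
| `c` | contrast coefficient on the restored residual | — | 1.2 |
| `lowpass_sigma` | Gaussian lowpass width, kernel truncated at radius ⌈3σ⌉ | px | 1.5 |
| `connectivity` | pixel adjacency for area opening and reconstruction | — | 8 |
| `boundary` | image extension: symmetric (edge-replicating mirror) or periodic | — | symmetric |

`K`, `P`, `h`, `t`, `s_size`, `c` defaults are the published operating point.
`K` is interpreted as the window *half*-width (the common NLM convention; the
alternative side-length reading is runnable by passing a different `K`).
`lowpass_sigma = 1.5` px and 8-connectivity are this package's choices where
the method leaves them open: 1.5 px suppresses pixel-scale noise in the base
without flattening organ-scale structure, and 8-connectivity is the standard
2-D morphology default; both are exposed as flags. `t` lives on the same
[0, 1] intensity scale as `h`.

## Numerical choices

* **Prefix-sum convention.** The (2P+1)-sample box sum is read as
  `S(s+P) − S(s−P−1)` with an exclusive prefix (`S(−1) = 0`), the only
  convention consistent with the sliding-window definition of the weights.
* **Arithmetic.** Double precision throughout; the per-translation
  accumulation order is row-major and fixed, so results are bit-reproducible
  across runs. The fast and sliding-window paths agree to ~1e-14 on random
  images (contract: 1e-8); the residual split, recomposition and `c`-linearity
  identities hold to machine rounding exactly.
* **Reconstruction.** Grayscale geodesic reconstruction uses the hybrid
  algorithm from scikit-image; the test suite holds it to 1e-12 against an
  independent iterated geodesic-dilation fixed-point oracle and checks
  idempotence. Reconstruction can propagate a marker arbitrarily far, so the
  morphological stage is never tiled.
* **Tiling.** NLM and the lowpass have finite receptive fields (`K+P` and
  `⌈3σ⌉` px), so tiles with at least that much halo reproduce the untiled
  result to ~1e-15 (contract 1e-10); an insufficient halo raises a
  configuration error rather than degrading silently.
* **Clipping.** No intermediate is clipped — `I_out` may leave [0, 1] when
  `c > 1` and noisy images keep their negative excursions — so the algebraic
  identities are exact. Clipping happens once, on export to 8/16-bit formats
  (round-half-even).
* **Degenerate inputs.** `K=0` returns the input bit-exactly; a 1×1 image with
  `K=P=0` passes through; a constant image is a fixed point of every stage.

## Synthetic data

`generate_phantom` emulates the gross geometry of an abdominal CT slice:
overlapping ellipses filled with exact tissue-like gray levels
(0.10–0.85), sharp boundaries, and a few small ±0.06 "lesion" discs; default
size 128×128 with 6 ellipses and 3 lesions. `add_gaussian_noise` adds seeded
i.i.d. Gaussian noise with std quoted on the 8-bit scale (σ₈/255), spanning
the σ₈ = 5–30 low-dose range, unclipped.

What the phantom does **not** reproduce: streak artifacts and spatially
correlated reconstruction noise, texture inside organs, the scanner's
modulation transfer function, and DICOM intensity calibration. Passing tests
therefore demonstrate the algebraic and statistical correctness of the
implementation and its denoising behaviour under additive Gaussian noise on
piecewise-constant content — not clinical image quality, which depends on
real projection noise and was never in scope.

Measured on these conditions (20 seeded repetitions per noise level, default
parameters, reported by `scripts/acceptance.py`): PSNR gains of roughly
+5.5 dB at σ₈=10, +6.5 dB at σ₈=20 and +4.2 dB at σ₈=30, with SSIM and RMSE
improving in 100 % of repetitions. The 128×128 problem size keeps the whole
evaluation in the seconds range; gains are not size-sensitive because every
stage is local.

## Known limitations

* 2-D single-channel images only; the math generalizes to 3-D but only d=2 is
  implemented.
* `h` acts on the *unnormalized* patch SSD, so its effective strength scales
  with (2P+1)²; changing `P` materially changes the meaning of a given `h`.
* At high noise (σ₈ ≈ 30) the NLM stage contributes little at the default
  `h`; most of the gain then comes from the lowpass base, and residual noise
  components larger than `s_size` pixels above threshold `t` can survive into
  the output.
* FSIM, sinogram-domain noise simulation and DICOM I/O are explicitly out of
  scope; the metric module exposes PSNR/RMSE/SSIM and line profiles only.
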