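"""Denoise a synthetic low-dose phantom with the published default parameters.

Builds a 128x128 piecewise-constant abdominal-style phantom, degrades it
with additive Gaussian noise of std 20 on the 8-bit scale, runs the full
two-stage pipeline (prefix-sum NLM, then morphological residual
processing) and prints PSNR/SSIM/RMSE before and after.  Higher PSNR/SSIM
and lower RMSE mean the output is closer to the clean phantom.
"""

import numpy as np

import ctdenoise as ctd

phantom = ctd.generate_phantom(ctd.PhantomSpec(height=128, width=128, seed=7))
noisy = ctd.add_gaussian_noise(phantom, ctd.NoiseSpec(sigma8=20, seed=7))

result = ctd.denoise(noisy)  # P=5, K=3, h=0.15, t=0.15, s=3, c=1.2

noisy_c = np.clip(noisy, 0, 1)
out_c = np.clip(result.out, 0, 1)
before = ctd.compute_metrics(phantom, noisy_c)
after = ctd.compute_metrics(phantom, out_c)

print(f"noisy    : PSNR {before.psnr:6.2f} dB  SSIM {before.ssim:.4f}  RMSE {before.rmse:.4f}")
print(f"denoised : PSNR {after.psnr:6.2f} dB  SSIM {after.ssim:.4f}  RMSE {after.rmse:.4f}")
print(f"PSNR gain: {after.psnr - before.psnr:+.2f} dB "
      "(noise removed while edges are restored from the residual)")
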