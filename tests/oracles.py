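"""Independent reference implementations used only by the test suite.

These deliberately avoid the code paths they are checking: pure-Python
loops for NLM weights and outputs, direct summation for box sums, and
iterated geodesic dilation for reconstruction.
"""

import numpy as np
from scipy import ndimage


def pad(img, margin, mode):
    return np.pad(img, margin, mode="symmetric" if mode == "symmetric" else "wrap")


def nlm_loops(img, K, P, h, mode="symmetric"):
    """Fully looped non-local means (flat patch kernel) for tiny images."""
    H, W = img.shape
    m = K + P
    E = pad(img, m, mode)
    out = np.empty_like(img, dtype=np.float64)
    for i in range(H):
        for j in range(W):
            num = 0.0
            Z = 0.0
            for dr in range(-K, K + 1):
                for dc in range(-K, K + 1):
                    ssd = 0.0
                    for pr in range(-P, P + 1):
                        for pc in range(-P, P + 1):
                            a = E[m + i + pr, m + j + pc]
                            b = E[m + i + dr + pr, m + j + dc + pc]
                            ssd += (a - b) ** 2
                    w = 1.0 / (1.0 + ssd**2 / h**2)
                    num += w * E[m + i + dr, m + j + dc]
                    Z += w
            out[i, j] = num / Z
    return out


def patch_ssd_loops(E, center, d, P):
    """Direct double-loop patch sum of squared differences on an extended image."""
    r, c = center
    dr, dc = d
    total = 0.0
    for pr in range(-P, P + 1):
        for pc in range(-P, P + 1):
            total += (E[r + pr, c + pc] - E[r + pr + dr, c + pc + dc]) ** 2
    return total


def box_sum_loops(D, r0, r1, c0, c1):
    """Direct summation of D over the inclusive box [r0..r1] x [c0..c1]."""
    return float(np.sum(D[r0 : r1 + 1, c0 : c1 + 1]))


def windowed_box_mean(img, K, mode="symmetric"):
    """Uniform mean over the (2K+1)^2 search window — the h->infinity limit of NLM."""
    return ndimage.uniform_filter(
        img, size=2 * K + 1, mode="reflect" if mode == "symmetric" else "wrap"
    )


def reconstruct_by_iterated_dilation(mask_img, marker, connectivity=8):
    """Geodesic reconstruction by dilation, iterated to the fixed point."""
    if connectivity == 8:
        fp = np.ones((3, 3), dtype=bool)
    else:
        fp = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    cur = marker.astype(np.float64).copy()
    while True:
        nxt = np.minimum(ndimage.grey_dilation(cur, footprint=fp), mask_img)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def local_ssim_center(x, y, K1=0.01, K2=0.03, sigma=1.5, data_range=1.0):
    """Local SSIM at the centre of an 11x11 pair, straight from the formula."""
    assert x.shape == y.shape == (11, 11)
    ax = np.arange(11) - 5
    g1 = np.exp(-(ax**2) / (2 * sigma**2))
    w = np.outer(g1, g1)
    w /= w.sum()
    ux, uy = np.sum(w * x), np.sum(w * y)
    vx = np.sum(w * (x - ux) ** 2)
    vy = np.sum(w * (y - uy) ** 2)
    cov = np.sum(w * (x - ux) * (y - uy))
    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    return ((2 * ux * uy + C1) * (2 * cov + C2)) / (
        (ux**2 + uy**2 + C1) * (vx + vy + C2)
    )
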