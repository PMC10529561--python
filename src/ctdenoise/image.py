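"""The grayscale image container used throughout the package.

A ``GrayImage`` is simply a 2-D ``float64`` numpy array of finite
intensities, nominally in ``[0, 1]``.  All filtering stages consume and
produce such arrays; file I/O (``ctdenoise.image_io``) converts to and
from integer pixel formats at the boundary of the package only.
"""

from __future__ import annotations

import numpy as np
import numpy.typing as npt

from .errors import ContractError

GrayImage = npt.NDArray[np.float64]
"""2-D float64 array of finite intensities, nominal range [0, 1]."""


def as_gray_image(arr: npt.ArrayLike) -> GrayImage:
    """Coerce ``arr`` to a valid 2-D float64 image.

    Raises
    ------
    ContractError
        If the input is not 2-D, is empty, or contains non-finite values.
    """
    out = np.asarray(arr, dtype=np.float64)
    if out.ndim != 2:
        raise ContractError(f"expected a 2-D image, got ndim={out.ndim}")
    if out.shape[0] < 1 or out.shape[1] < 1:
        raise ContractError(f"image must be at least 1x1, got shape {out.shape}")
    if not np.all(np.isfinite(out)):
        raise ContractError("image contains non-finite values")
    return out


def check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ContractError(f"shape mismatch: {a.shape} vs {b.shape}")
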