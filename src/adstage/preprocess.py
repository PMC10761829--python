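"""Image loading, linear-stretch contrast enhancement, and brain masking.

Input images are single 2-D slices with ``k``-bit integer intensities
(``k = 8`` for the dementia MRI sets this package targets).  Contrast
enhancement is a linear stretch that maps the slice minimum to 0 and the
slice maximum to ``2**k - 1``; because the map is affine and monotone it
changes no intensity *ordering* and therefore no tissue area ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import imageio.v3 as iio
from scipy import ndimage

# ITU-R BT.601 luminance weights for RGB -> grey conversion
_BT601 = np.array([0.299, 0.587, 0.114])


def load_image(path) -> np.ndarray:
    """Load a PNG/JPEG slice as an 8-bit single-channel image.

    RGB inputs are converted to BT.601 luminance and quantised back to
    8 bits.  Returns a 2-D ``uint8`` array of shape (M, N).

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    ValueError
        If the decoded image has zero pixels.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _BT601
        arr = np.floor(arr + 0.5)
    arr = np.asarray(arr)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    return np.clip(arr, 0, 255).astype(np.uint8)


def linear_stretch(image: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Linearly stretch intensities to cover the full ``[0, 2**k - 1]`` range.

    Each pixel is mapped through
    ``(I - I_min) / (I_max - I_min) * (2**k - 1)`` and rounded half-up to
    the nearest integer.  A constant image (``I_max == I_min``) has no
    defined stretch; it is returned as all zeros with a warning so that
    batch runs survive blank slices.
    """
    image = _validate_image(image, bit_depth)
    lo = int(image.min())
    hi = int(image.max())
    full = (1 << bit_depth) - 1
    if hi == lo:
        warnings.warn("constant image: linear stretch is undefined, returning zeros",
                      stacklevel=2)
        return np.zeros_like(image)
    scaled = (image.astype(np.float64) - lo) / (hi - lo) * full
    out = np.floor(scaled + 0.5)  # round half-up; np.round would round half-even
    return np.clip(out, 0, full).astype(image.dtype)


def compute_brain_mask(
    image: np.ndarray,
    threshold: int = 0,
    closing_size: int = 3,
) -> np.ndarray:
    """Foreground (brain) mask for a slice with a dark background.

    Pixels strictly above ``threshold`` are taken as foreground, the
    result is morphologically closed with a ``closing_size`` square,
    holes are filled, and only the largest connected component is kept —
    so interior voids (ventricles, atrophied tissue) stay inside the
    mask while detached background specks are dropped.

    Raises
    ------
    ValueError
        If no pixel exceeds the threshold.
    """
    fg = np.asarray(image) > threshold
    if not fg.any():
        raise ValueError("empty brain mask: no pixel above background threshold")
    if closing_size > 1:
        fg = ndimage.binary_closing(fg, structure=np.ones((closing_size, closing_size)))
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return fg.astype(np.uint8)


def _validate_image(image: np.ndarray, bit_depth: int) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {image.shape}")
    full = (1 << bit_depth) - 1
    if image.min() < 0 or image.max() > full:
        raise ValueError(f"intensities outside [0, {full}] for bit depth {bit_depth}")
    return image
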