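"""Grey/white matter segmentation from the two thresholds.

Grey matter occupies the mid-intensity band strictly between ``Th1`` and
``Th2``; white matter everything strictly above ``Th2``.  Pixels equal
to a threshold belong to neither tissue.  Two scalar atrophy summaries
follow: GWR, the grey-to-white pixel-count ratio, and shrinkage, the
fraction of the brain mask still occupied by tissue — atrophy replaces
tissue with dark void, so shrinkage falls as dementia progresses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TissueSegmentation:
    """Binary tissue masks plus per-tissue intensity statistics.

    Volumes are 2-D pixel counts (single-slice inputs).  Statistics use
    the population convention (divide by n); the skew of a zero-spread
    tissue is defined as 0.  Undefined statistics (empty tissue) are NaN.
    """

    grey_mask: np.ndarray
    white_mask: np.ndarray
    brain_mask: np.ndarray
    grey_volume: int
    white_volume: int
    grey_mean: float
    white_mean: float
    grey_std: float
    white_std: float
    grey_skew: float
    white_skew: float
    gwr: float
    shrinkage: float


def segment_tissues(
    image: np.ndarray,
    th1: float,
    th2: float,
    brain_mask: np.ndarray | None = None,
) -> TissueSegmentation:
    """Threshold an image into grey and white tissue and summarise both.

    ``brain_mask`` (1 = inside the head) is only used for shrinkage; if
    omitted, shrinkage is NaN.  Raises ``ValueError`` on a bad threshold
    pair or an all-zero mask.
    """
    image = np.asarray(image)
    if not th1 < th2:
        raise ValueError(f"need th1 < th2, got {th1} >= {th2}")
    grey = (image > th1) & (image < th2)
    white = image > th2
    gv = int(grey.sum())
    wv = int(white.sum())
    g_stats = _moments(image[grey])
    w_stats = _moments(image[white])
    gwr = gv / wv if wv > 0 else (0.0 if gv == 0 else np.nan)
    if brain_mask is not None:
        mask = np.asarray(brain_mask).astype(bool)
        m = int(mask.sum())
        if m == 0:
            raise ValueError("empty brain mask")
        shrink = (gv + wv) / m
    else:
        mask = np.zeros_like(image, dtype=bool)
        shrink = np.nan
    return TissueSegmentation(
        grey_mask=grey.astype(np.uint8), white_mask=white.astype(np.uint8),
        brain_mask=mask.astype(np.uint8),
        grey_volume=gv, white_volume=wv,
        grey_mean=g_stats[0], white_mean=w_stats[0],
        grey_std=g_stats[1], white_std=w_stats[1],
        grey_skew=g_stats[2], white_skew=w_stats[2],
        gwr=gwr, shrinkage=shrink,
    )


def compute_gwr(seg: TissueSegmentation) -> float:
    """Grey-to-white matter ratio (pixel counts); 0 for empty grey."""
    if seg.white_volume == 0:
        raise ValueError("GWR undefined: empty white matter")
    return seg.grey_volume / seg.white_volume


def compute_shrinkage(seg: TissueSegmentation) -> float:
    """Tissue fraction of the brain mask: (grey + white) / mask pixels."""
    m = int(np.asarray(seg.brain_mask).sum())
    if m == 0:
        raise ValueError("shrinkage undefined: empty brain mask")
    return (seg.grey_volume + seg.white_volume) / m


def _moments(pixels: np.ndarray) -> tuple[float, float, float]:
    """Population mean, std, and skew of a pixel set; NaNs when empty."""
    if pixels.size == 0:
        return (np.nan, np.nan, np.nan)
    x = pixels.astype(np.float64)
    mean = float(x.mean())
    std = float(x.std())
    if std == 0.0:
        return (mean, 0.0, 0.0)
    skew = float(((x - mean) ** 3).mean() / std**3)
    return (mean, std, skew)
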