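"""The 17-feature atrophy descriptor of a single brain slice.

The fixed feature order is::

    th1, th2, alpha1, alpha2, d1, d2, d3,
    grey_volume, white_volume, grey_mean, white_mean,
    grey_std, white_std, grey_skew, white_skew, gwr, shrinkage

Seven come from the smoothed-histogram geometry (the two thresholds, two
slopes, three distances), eight are per-tissue moments (volume, mean,
standard deviation, skewness of grey and white matter), and two are the
derived atrophy ratios GWR and shrinkage.  The third moment rounds out
the per-tissue statistics to reach the full 17; swap in alternatives via
subclassing if a different completion is preferred.

:class:`AtrophyFeatureExtractor` is a stateless scikit-learn transformer:
``transform`` maps a stack or list of 2-D slices to an ``(n, 17)``
matrix, so it drops into sklearn pipelines in front of any classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import preprocess
from .histogram import FilterSpec, compute_histogram, design_lowpass, smooth_histogram
from .segmentation import segment_tissues
from .thresholds import ThresholdingFailure, find_thresholds

FEATURE_NAMES: tuple[str, ...] = (
    "th1", "th2", "alpha1", "alpha2", "d1", "d2", "d3",
    "grey_volume", "white_volume", "grey_mean", "white_mean",
    "grey_std", "white_std", "grey_skew", "white_skew", "gwr", "shrinkage",
)


@dataclass
class FeatureRecord:
    """One image's extraction outcome: a vector or a failure reason."""

    source_id: str
    values: np.ndarray | None
    failure: str | None = None
    label: int | None = None

    @property
    def ok(self) -> bool:
        return self.failure is None


class AtrophyFeatureExtractor(BaseEstimator, TransformerMixin):
    """Histogram-threshold feature extraction as a sklearn transformer.

    Parameters
    ----------
    bit_depth : int
        Bits per pixel; fixes the histogram length at ``2**bit_depth``.
    stretch : bool
        Apply the linear contrast stretch before analysis.
    passband, atten_db, transition : float
        Lowpass design for the histogram envelope (fractions of Nyquist
        and dB; see :class:`~adstage.histogram.FilterSpec`).
    noise_floor : float
        Relative envelope level below which smoothed values are treated
        as filter leakage, not structure.
    th1_rule : {"second_minimum", "first_maximum"}
        How the lower threshold is picked from the extrema sequence.
    normalize_heights : bool
        Use probability-normalised envelope heights in the geometry
        features instead of raw counts.
    mask_mode : {"tissue", "zero"}
        Brain mask from tissue pixels (``> Th1``, robust to background
        noise) or from any non-zero pixel (pure-black backgrounds).
    closing_size : int
        Structuring-element size for the mask's morphological closing.
    """

    def __init__(self, bit_depth: int = 8, stretch: bool = True,
                 passband: float = 0.005, atten_db: float = 60.0,
                 transition: float = 0.15, noise_floor: float = 1e-3,
                 th1_rule: str = "second_minimum",
                 normalize_heights: bool = False,
                 mask_mode: str = "tissue", closing_size: int = 3):
        self.bit_depth = bit_depth
        self.stretch = stretch
        self.passband = passband
        self.atten_db = atten_db
        self.transition = transition
        self.noise_floor = noise_floor
        self.th1_rule = th1_rule
        self.normalize_heights = normalize_heights
        self.mask_mode = mask_mode
        self.closing_size = closing_size

    # -- sklearn API ----------------------------------------------------
    def fit(self, X=None, y=None):
        """Design the lowpass filter; the extractor learns nothing else."""
        self.filter_spec_ = design_lowpass(
            FilterSpec(self.passband, self.atten_db, self.transition))
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        """Extract features for each image; failed rows are all-NaN."""
        rows = [self.extract(img, source_id=str(i)) for i, img in enumerate(X)]
        out = np.full((len(rows), len(FEATURE_NAMES)), np.nan)
        for i, rec in enumerate(rows):
            if rec.ok:
                out[i] = rec.values
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)

    # -- core -----------------------------------------------------------
    def extract(self, image: np.ndarray, source_id: str = "",
                label: int | None = None) -> FeatureRecord:
        """Run the full pipeline on one slice.

        Degenerate slices (constant, unimodal after smoothing, empty
        tissue) come back as failure records rather than exceptions so a
        batch run can log and continue.
        """
        if not hasattr(self, "filter_spec_"):
            self.fit()
        fail = lambda why: FeatureRecord(source_id, None, why, label)
        image = np.asarray(image)
        if self.stretch:
            if image.max() == image.min():
                return fail("constant image")
            image = preprocess.linear_stretch(image, self.bit_depth)
        counts = compute_histogram(image, self.bit_depth)
        smoothed = smooth_histogram(counts, self.filter_spec_)
        try:
            geom = find_thresholds(
                smoothed, counts, noise_floor=self.noise_floor,
                th1_rule=self.th1_rule,
                normalize_heights=self.normalize_heights)
        except ThresholdingFailure as exc:
            return fail(f"thresholding failed: {exc}")
        mask_thr = int(geom.th1) if self.mask_mode == "tissue" else 0
        try:
            mask = preprocess.compute_brain_mask(
                image, threshold=mask_thr, closing_size=self.closing_size)
        except ValueError as exc:
            return fail(str(exc))
        seg = segment_tissues(image, geom.th1, geom.th2, mask)
        if seg.white_volume == 0:
            return fail("empty white matter")
        if seg.grey_volume == 0:
            return fail("empty grey matter")
        values = np.array([
            geom.th1, geom.th2, geom.alpha1, geom.alpha2,
            geom.d1, geom.d2, geom.d3,
            seg.grey_volume, seg.white_volume,
            seg.grey_mean, seg.white_mean,
            seg.grey_std, seg.white_std,
            seg.grey_skew, seg.white_skew,
            seg.gwr, seg.shrinkage,
        ])
        if not np.all(np.isfinite(values)):
            bad = FEATURE_NAMES[int(np.argmax(~np.isfinite(values)))]
            return fail(f"non-finite feature {bad}")
        return FeatureRecord(source_id, values, None, label)


def extract_features(image: np.ndarray, **params) -> FeatureRecord:
    """One-shot extraction on a single image (see AtrophyFeatureExtractor)."""
    return AtrophyFeatureExtractor(**params).fit().extract(image)


def extract_table(
    images,
    labels=None,
    ids=None,
    extractor: AtrophyFeatureExtractor | None = None,
) -> tuple[pd.DataFrame, list[FeatureRecord]]:
    """Batch extraction into a feature table.

    Returns a DataFrame with ``source_id``, ``label`` and the 17 feature
    columns (successful images only, in input order) plus the list of
    failure records.
    """
    if extractor is None:
        extractor = AtrophyFeatureExtractor()
    extractor.fit()
    if ids is None:
        ids = [f"img{i:05d}" for i in range(len(images))]
    if labels is None:
        labels = [None] * len(images)
    records = [extractor.extract(img, source_id=sid, label=lab)
               for img, sid, lab in zip(images, ids, labels)]
    good = [r for r in records if r.ok]
    failures = [r for r in records if not r.ok]
    table = pd.DataFrame(
        [r.values for r in good], columns=list(FEATURE_NAMES))
    table.insert(0, "label", [r.label for r in good])
    table.insert(0, "source_id", [r.source_id for r in good])
    return table, failures
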