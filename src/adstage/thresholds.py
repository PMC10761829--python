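"""Valley-based threshold selection on the smoothed histogram.

Two intensity thresholds are read off the local minima of the smoothed
envelope: ``Th1`` separates background from grey matter and ``Th2``
separates grey from white matter.  With three or more interior minima
the rule is "second and last minimum" — the first minimum is the notch
immediately after the empty-background spike, so it is skipped; with
exactly two interior minima there is no such notch and the two valleys
are used directly.  The absolute maximum ``(x3, y3)`` of the envelope
anchors the slope/distance geometry features.

Minima sitting at the ends of the occupied intensity range (or created
beyond it by filter spill-over) are not tissue boundaries and are never
selected; this also makes the geometry invariant to appending
zero-count bins past the occupied range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np


class Extremum(NamedTuple):
    """A local extremum; plateaus are reported at their midpoint bin.

    ``start``/``end`` give the inclusive plateau extent (equal to ``bin``
    for a single-bin extremum).
    """

    bin: int
    value: float
    start: int
    end: int


@dataclass
class ExtremaSet:
    minima: list[Extremum]
    maxima: list[Extremum]


class ThresholdingFailure(Exception):
    """Raised when too few distinct valleys exist to place two thresholds."""

    def __init__(self, message: str, extrema: ExtremaSet | None = None):
        super().__init__(message)
        self.extrema = extrema


@dataclass
class ThresholdGeometry:
    """Threshold points and the derived slope/distance features.

    Coordinates live in the (intensity bin, envelope height) plane:
    ``(x1, y1)`` and ``(x2, y2)`` are the selected valleys (``Th1 = x1``,
    ``Th2 = x2``), ``(x3, y3)`` the absolute maximum.  ``alpha1``/
    ``alpha2`` are the slopes from the maximum to each valley and
    ``d1, d2, d3`` the pairwise Euclidean distances.
    """

    x1: float
    y1: float
    x2: float
    y2: float
    x3: float
    y3: float
    th1: float
    th2: float
    alpha1: float = np.nan
    alpha2: float = np.nan
    d1: float = np.nan
    d2: float = np.nan
    d3: float = np.nan


def find_local_extrema(values: np.ndarray) -> ExtremaSet:
    """Strict local minima and maxima of a sequence, with plateau handling.

    A run of equal values is a single candidate reported at its midpoint
    bin; it is a minimum (maximum) when it lies strictly below (above)
    every flanking non-plateau value it has.  Endpoint runs have a single
    flank and are eligible, so a monotone sequence has one minimum and
    one maximum at its ends.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("expected a 1-D sequence of length >= 3")
    # run-length compress equal-value plateaus
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(values) - 1]))
    vals = values[starts]
    minima, maxima = [], []
    for i in range(len(starts)):
        left = vals[i - 1] if i > 0 else None
        right = vals[i + 1] if i + 1 < len(starts) else None
        ext = Extremum(int((starts[i] + ends[i]) // 2), float(vals[i]),
                       int(starts[i]), int(ends[i]))
        if (left is None or vals[i] < left) and (right is None or vals[i] < right):
            minima.append(ext)
        if (left is None or vals[i] > left) and (right is None or vals[i] > right):
            maxima.append(ext)
    return ExtremaSet(minima=minima, maxima=maxima)


def extract_thresholds(
    extrema: ExtremaSet,
    support: tuple[int, int] | None = None,
    th1_rule: str = "second_minimum",
) -> ThresholdGeometry:
    """Select ``Th1``/``Th2`` and the absolute-maximum anchor from extrema.

    Parameters
    ----------
    extrema : ExtremaSet
        Output of :func:`find_local_extrema`.
    support : (low, high), optional
        Occupied intensity range.  Only minima whose plateau lies
        strictly inside it are threshold candidates; the maximum is
        restricted to it.  ``None`` keeps every non-endpoint extremum.
    th1_rule : {"second_minimum", "first_maximum"}
        ``Th1`` from the valley sequence (default) or, alternatively,
        from the first interior peak.

    Raises
    ------
    ThresholdingFailure
        If fewer than two distinct interior minima exist.  The failure
        carries the extrema found so a caller may retry with different
        smoothing.
    """
    if support is None:
        lo = min((e.start for e in extrema.minima + extrema.maxima), default=0)
        hi = max((e.end for e in extrema.minima + extrema.maxima), default=0)
    else:
        lo, hi = support
    interior_min = [e for e in extrema.minima if e.start > lo and e.end < hi]
    in_support_max = [e for e in extrema.maxima if lo <= e.bin <= hi]
    if len(interior_min) < 2:
        raise ThresholdingFailure(
            f"need >= 2 interior minima, found {len(interior_min)}", extrema)
    last = interior_min[-1]
    if th1_rule == "second_minimum":
        # skip the post-background notch when there is one to skip
        first = interior_min[1] if len(interior_min) >= 3 else interior_min[0]
    elif th1_rule == "first_maximum":
        inner_peaks = [e for e in extrema.maxima if e.start > lo and e.end < hi]
        if not inner_peaks:
            raise ThresholdingFailure("no interior maximum for th1_rule", extrema)
        first = inner_peaks[0]
    else:
        raise ValueError(f"unknown th1_rule {th1_rule!r}")
    if first.bin >= last.bin:
        raise ThresholdingFailure(
            "selected minima do not give Th1 < Th2", extrema)
    if not in_support_max:
        raise ThresholdingFailure("no maximum inside the occupied range", extrema)
    peak = max(in_support_max, key=lambda e: (e.value, -e.bin))  # ties: smallest bin
    return ThresholdGeometry(
        x1=float(first.bin), y1=first.value,
        x2=float(last.bin), y2=last.value,
        x3=float(peak.bin), y3=peak.value,
        th1=float(first.bin), th2=float(last.bin),
    )


def compute_geometry(points: ThresholdGeometry) -> ThresholdGeometry:
    """Fill in slopes and distances between the threshold points.

    Slopes from the peak to each valley; distances are Euclidean in the
    (bin, height) plane.  A vertical configuration (``x3 == x1`` or
    ``x3 == x2``) gets a signed-infinity slope; distances are always
    defined.
    """
    p = points
    p.alpha1 = _slope(p.x1, p.y1, p.x3, p.y3)
    p.alpha2 = _slope(p.x2, p.y2, p.x3, p.y3)
    p.d1 = float(np.hypot(p.x3 - p.x1, p.y3 - p.y1))
    p.d2 = float(np.hypot(p.x3 - p.x2, p.y3 - p.y2))
    p.d3 = float(np.hypot(p.x2 - p.x1, p.y2 - p.y1))
    return p


def find_thresholds(
    smoothed: np.ndarray,
    counts: np.ndarray | None = None,
    noise_floor: float = 1e-3,
    th1_rule: str = "second_minimum",
    normalize_heights: bool = False,
) -> ThresholdGeometry:
    """Full threshold selection: floor ripple, trim support, pick valleys.

    Values below ``noise_floor`` times the envelope peak — the filter's
    own stopband leakage — are zeroed so ringing around strong spikes
    does not masquerade as valleys.  ``counts`` (the raw histogram)
    defines the occupied range; without it the whole axis is used.
    With ``normalize_heights`` the y-coordinates entering the geometry
    are divided by the pixel total, making distances independent of
    image size (default keeps raw counts, as the feature definitions
    are written).
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    floored = smoothed.copy()
    if noise_floor > 0 and floored.max() > 0:
        floored[floored < noise_floor * floored.max()] = 0.0
    if counts is not None:
        occupied = np.flatnonzero(np.asarray(counts))
        if occupied.size == 0:
            raise ThresholdingFailure("empty histogram")
        support = (int(occupied[0]), int(occupied[-1]))
    else:
        support = (0, len(smoothed) - 1)
    geom = extract_thresholds(find_local_extrema(floored), support=support,
                              th1_rule=th1_rule)
    if normalize_heights:
        total = float(np.asarray(counts).sum()) if counts is not None else 1.0
        if total > 0:
            for attr in ("y1", "y2", "y3"):
                setattr(geom, attr, getattr(geom, attr) / total)
    return compute_geometry(geom)


def _slope(xa: float, ya: float, x3: float, y3: float) -> float:
    dx = x3 - xa
    dy = y3 - ya
    if dx == 0:
        return float(np.copysign(np.inf, dy)) if dy != 0 else np.nan
    return float(dy / dx)
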