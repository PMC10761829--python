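"""Extrema detection, threshold selection, and the slope/distance geometry."""

import numpy as np
import pytest

from adstage import (ThresholdGeometry, ThresholdingFailure, compute_geometry,
                     compute_histogram, extract_thresholds, find_local_extrema,
                     find_thresholds, smooth_histogram)


def brute_force_extrema(values):
    """Naive O(L^2) oracle: for each run of equal values, compare the
    nearest differing values on each side."""
    values = np.asarray(values, float)
    minima, maxima = [], []
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] == values[i]:
            j += 1
        left = values[i - 1] if i > 0 else None
        right = values[j + 1] if j + 1 < len(values) else None
        mid = (i + j) // 2
        if (left is None or values[i] < left) and (right is None or values[i] < right):
            minima.append(mid)
        if (left is None or values[i] > left) and (right is None or values[i] > right):
            maxima.append(mid)
        i = j + 1
    return minima, maxima


class TestFindLocalExtrema:
    def test_hand_example(self):
        ext = find_local_extrema([3, 1, 2, 0, 4])
        assert [e.bin for e in ext.minima] == [1, 3]
        assert [e.bin for e in ext.maxima] == [0, 2, 4]

    def test_monotone_sequence_endpoints(self):
        ext = find_local_extrema(np.arange(10.0))
        assert [e.bin for e in ext.minima] == [0]
        assert [e.bin for e in ext.maxima] == [9]

    def test_plateau_midpoint(self):
        ext = find_local_extrema([5, 2, 2, 2, 5])
        assert [e.bin for e in ext.minima] == [2]
        assert ext.minima[0].start == 1 and ext.minima[0].end == 3

    def test_alternation(self, rng):
        values = rng.integers(0, 20, 100).astype(float)
        ext = find_local_extrema(values)
        merged = sorted([(e.bin, "min") for e in ext.minima]
                        + [(e.bin, "max") for e in ext.maxima])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    @pytest.mark.parametrize("kind", ["float", "int"])
    def test_matches_brute_force_oracle(self, kind, rng):
        for _ in range(200):
            n = int(rng.integers(3, 80))
            if kind == "float":
                values = rng.random(n)
            else:  # integer values create plateaus
                values = rng.integers(0, 5, n).astype(float)
            ext = find_local_extrema(values)
            mins, maxs = brute_force_extrema(values)
            assert [e.bin for e in ext.minima] == mins
            assert [e.bin for e in ext.maxima] == maxs

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_local_extrema([1.0, 2.0])


class TestExtractThresholds:
    def _extrema(self, values):
        return find_local_extrema(np.asarray(values, float))

    def test_second_and_last_of_three(self):
        # minima at 10, 60, 160; peak at 30
        values = np.ones(200)
        for b, v in [(10, 0.2), (60, 0.3), (160, 0.1)]:
            values[b] = v
        values[30] = 9.0
        geom = extract_thresholds(self._extrema(values), support=(0, 199))
        assert geom.th1 == 60 and geom.th2 == 160
        assert geom.x3 == 30 and geom.y3 == 9.0

    def test_two_minima_fall_back_to_first_and_last(self):
        values = np.ones(100)
        values[20] = 0.1
        values[70] = 0.2
        values[40] = 5.0
        geom = extract_thresholds(self._extrema(values), support=(0, 99))
        assert geom.th1 == 20 and geom.th2 == 70

    def test_single_minimum_fails(self):
        values = np.ones(50)
        values[25] = 0.0
        with pytest.raises(ThresholdingFailure) as exc:
            extract_thresholds(self._extrema(values), support=(0, 49))
        assert exc.value.extrema is not None

    def test_endpoint_minima_not_selected(self):
        # decaying tail: an endpoint minimum must never become Th2
        values = np.ones(100)
        values[20] = 0.1
        values[70] = 0.2
        values[40] = 5.0
        values[99] = 0.0  # endpoint dip
        geom = extract_thresholds(self._extrema(values), support=(0, 99))
        assert geom.th2 == 70

    def test_first_maximum_rule(self):
        values = np.ones(200)
        for b, v in [(10, 0.2), (60, 0.3), (160, 0.1)]:
            values[b] = v
        values[30] = 9.0
        geom = extract_thresholds(self._extrema(values), support=(0, 199),
                                  th1_rule="first_maximum")
        assert geom.th1 == 30 and geom.th2 == 160

    def test_phantom_histogram_valleys(self, noiseless_phantom):
        img, _ = noiseless_phantom
        counts = compute_histogram(img)
        geom = find_thresholds(smooth_histogram(counts), counts)
        assert 0 < geom.th1 < 100 < geom.th2 < 200

    def test_zero_bin_append_invariance(self, noiseless_phantom):
        img, _ = noiseless_phantom
        counts = compute_histogram(img)
        geom = find_thresholds(smooth_histogram(counts), counts)
        padded = np.concatenate([counts, np.zeros(64, dtype=counts.dtype)])
        geom2 = find_thresholds(smooth_histogram(padded), padded)
        for attr in ("th1", "th2", "d1", "d2", "d3", "alpha1", "alpha2"):
            assert getattr(geom, attr) == pytest.approx(getattr(geom2, attr),
                                                        rel=1e-9)


class TestComputeGeometry:
    def _geom(self, p1, p2, p3):
        return ThresholdGeometry(x1=p1[0], y1=p1[1], x2=p2[0], y2=p2[1],
                                 x3=p3[0], y3=p3[1], th1=p1[0], th2=p2[0])

    def test_three_four_five_triangle(self):
        g = compute_geometry(self._geom((0, 0), (3, 4), (0, 0)))
        assert g.d1 == 0 and g.d3 == 5 and g.d2 == 5

    def test_hand_slope_and_distance(self):
        g = compute_geometry(self._geom((10, 2), (30, 0), (20, 12)))
        assert g.alpha1 == pytest.approx(1.0)
        assert g.d1 == pytest.approx(np.sqrt(200))

    def test_triangle_inequality_random(self, rng):
        for _ in range(300):
            pts = rng.random(6) * 100
            g = compute_geometry(self._geom(pts[:2], pts[2:4], pts[4:]))
            assert g.d3 <= g.d1 + g.d2 + 1e-9

    def test_vertical_slope_sentinel(self):
        g = compute_geometry(self._geom((10, 2), (30, 0), (10, 12)))
        assert np.isinf(g.alpha1) and g.alpha1 > 0
        assert g.d1 == pytest.approx(10.0)
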