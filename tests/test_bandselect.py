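"""Entropy/information-gain scorers, SG and gap-segment filters, peak logic.

Each numerical operation is checked against an independently written
brute-force oracle (explicit histogram counting, contingency-table
enumeration, normal-equations solve, literal segment averaging).
"""

import math
from bisect import bisect_right
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import savgol_coeffs

import specdx as sd
from specdx.bandselect import (
    GapSegParams,
    ScoreProfile,
    SGParams,
    _sg_weights,
    detect_peaks,
    smooth_profile,
    top_k,
)

# ---------------------------------------------------------------- oracles


def entropy_oracle(values, n_bins):
    """Literal equal-width histogram + Shannon formula."""
    lo, hi = min(values), max(values)
    if lo == hi:
        return 0.0
    edges = [lo + i * (hi - lo) / n_bins for i in range(1, n_bins)]
    counts = Counter(min(bisect_right(edges, v), n_bins - 1) for v in values)
    n = len(values)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def info_gain_oracle(values, labels, n_bins):
    """Enumerate the bin × class contingency table and apply the IG formula."""
    lo, hi = min(values), max(values)
    if lo == hi:
        bins = [0] * len(values)
    else:
        edges = [lo + i * (hi - lo) / n_bins for i in range(1, n_bins)]
        bins = [min(bisect_right(edges, v), n_bins - 1) for v in values]
    n = len(values)

    def h(items):
        counts = Counter(items)
        return -sum((c / len(items)) * math.log2(c / len(items)) for c in counts.values())

    ig = h(labels)
    for b in set(bins):
        members = [lab for bb, lab in zip(bins, labels) if bb == b]
        ig -= (len(members) / n) * h(members)
    return max(ig, 0.0)


def gap_segment_oracle(y, d_lambda, order, segment, gap):
    """Average segments, then finite-difference — written as literal loops."""
    n = len(y)
    half = segment + gap
    out = [math.nan] * n

    def seg_mean(start):
        return sum(y[start : start + segment]) / segment

    for i in range(half, n - half):
        left = seg_mean(i - gap - segment)
        right = seg_mean(i + gap + 1)
        if order == 1:
            out[i] = (right - left) / ((2 * gap + segment + 1) * d_lambda)
        else:
            centre = seg_mean(i - (segment - 1) // 2)
            d = (gap + (segment + 1) // 2) * d_lambda
            out[i] = (left + right - 2 * centre) / d**2
    return np.array(out)


# ------------------------------------------------------------ entropy / IG


class TestShannonEntropy:
    def test_zero_variability(self):
        assert sd.shannon_entropy([5, 5, 5, 5], 8) == 0.0

    def test_uniform_two_bins_is_one_bit(self):
        vals = [0.0, 0.1, 0.2, 0.3, 1.0, 1.1, 1.2, 1.3]
        assert sd.shannon_entropy(vals, 2) == pytest.approx(1.0)

    def test_eight_values_four_bins_two_bits(self):
        # 2 values per bin -> uniform over 4 bins
        assert sd.shannon_entropy([1, 2, 3, 4, 5, 6, 7, 8], 4) == pytest.approx(
            entropy_oracle([1, 2, 3, 4, 5, 6, 7, 8], 4)
        ) == pytest.approx(2.0)

    def test_rejects_empty_and_single(self):
        with pytest.raises(ValueError):
            sd.shannon_entropy([], 4)
        with pytest.raises(ValueError):
            sd.shannon_entropy([1.0], 4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=40),
        st.integers(2, 32),
    )
    def test_bounds_and_oracle_agreement(self, values, n_bins):
        h = sd.shannon_entropy(values, n_bins)
        assert 0.0 <= h <= math.log2(n_bins) + 1e-12
        assert h == pytest.approx(entropy_oracle(values, n_bins), abs=1e-9)


class TestInformationGain:
    def test_perfect_two_class_separation(self):
        vals = [0, 0, 0, 0, 10, 10, 10, 10]
        labs = ["a"] * 4 + ["b"] * 4
        assert sd.information_gain(vals, labs, 2) == pytest.approx(1.0)

    def test_constant_band_carries_nothing(self):
        assert sd.information_gain([3, 3, 3, 3], ["a", "a", "b", "b"], 4) == 0.0

    def test_single_class_returns_zero(self):
        assert sd.information_gain([1, 2, 3], ["a", "a", "a"], 2) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            sd.information_gain([1, 2], ["a"], 2)

    def test_three_class_contingency_oracle(self):
        vals = [0.0, 0.1, 1.0, 1.1, 1.2, 0.9]
        labs = ["a", "a", "b", "b", "c", "c"]
        expected = info_gain_oracle(vals, labs, 2)
        assert sd.information_gain(vals, labs, 2) == pytest.approx(expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_bounded_by_label_entropy_and_oracle(self, data):
        n = data.draw(st.integers(4, 30))
        vals = data.draw(
            st.lists(st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n)
        )
        labs = data.draw(st.lists(st.sampled_from("abc"), min_size=n, max_size=n))
        n_bins = data.draw(st.integers(2, 16))
        ig = sd.information_gain(vals, labs, n_bins)
        counts = Counter(labs)
        h_y = -sum((c / n) * math.log2(c / n) for c in counts.values())
        assert 0.0 <= ig <= h_y + 1e-12
        assert ig == pytest.approx(info_gain_oracle(vals, labs, n_bins), abs=1e-9)


class TestEntropyProfile:
    def test_constant_bands_give_zero_profile(self, tiny_set):
        s = sd.SpectraSet(
            grid=tiny_set.grid,
            reflectance=np.full((3, 5), 7.0),
            meta=tiny_set.meta,
        )
        prof = sd.entropy_profile(s, "entropy")
        np.testing.assert_array_equal(prof.scores, 0.0)

    def test_perfectly_separating_band_is_profile_max(self, tiny_set):
        refl = np.full((3, 5), 10.0)
        refl[:, 2] = [10.0, 40.0, 40.0]  # control vs N split
        s = sd.SpectraSet(grid=tiny_set.grid, reflectance=refl, meta=tiny_set.meta)
        prof = sd.entropy_profile(s, "infogain")
        assert int(np.argmax(prof.scores)) == 2


# ------------------------------------------------------------------ filters


class TestSavitzkyGolay:
    def test_reproduces_cubic_exactly(self):
        x = np.arange(60, dtype=float)
        y = 2.0 - 0.5 * x + 0.01 * x**2 + 3e-4 * x**3
        out = sd.savitzky_golay(y, SGParams(poly_order=3, window=11))
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_constant_unchanged(self):
        out = sd.savitzky_golay(np.full(30, 4.2), SGParams())
        np.testing.assert_allclose(out, 4.2, atol=1e-12)

    def test_window5_order2_central_weights(self):
        # normal-equations oracle for the classic quadratic 5-point smoother
        x = np.arange(-2.0, 3.0)
        a = np.vander(x, 3, increasing=True)
        oracle = np.linalg.solve(a.T @ a, a.T)[0]
        np.testing.assert_allclose(oracle, np.array([-3, 12, 17, 12, -3]) / 35.0)
        np.testing.assert_allclose(_sg_weights(5, 2), oracle, atol=1e-12)

    def test_interior_matches_scipy_coefficients(self):
        np.testing.assert_allclose(
            _sg_weights(11, 3), savgol_coeffs(11, 3, use="dot")[::-1], atol=1e-10
        )

    def test_even_window_aliased_up(self):
        assert SGParams(window=10).window == 11

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sd.savitzky_golay(np.arange(5.0), SGParams(window=11))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16), st.floats(-5, 5), st.floats(-5, 5))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=40), rng.normal(size=40)
        p = SGParams()
        lhs = sd.savitzky_golay(a * x + b * y, p)
        rhs = a * sd.savitzky_golay(x, p) + b * sd.savitzky_golay(y, p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestGapSegmentDerivative:
    GRID = sd.WavelengthGrid(400.0 + np.arange(50.0))

    def test_exact_slope_on_linear_ramp(self):
        wl = self.GRID.wavelengths_nm
        y = 3.0 + 0.05 * wl
        d = sd.gap_segment_derivative(y, self.GRID, GapSegParams(order=1))
        valid = np.isfinite(d)
        np.testing.assert_allclose(d[valid], 0.05, atol=1e-12)

    def test_exact_curvature_on_quadratic(self):
        wl = self.GRID.wavelengths_nm
        y = 0.001 * (wl - 420.0) ** 2
        d = sd.gap_segment_derivative(y, self.GRID, GapSegParams(order=2))
        valid = np.isfinite(d)
        np.testing.assert_allclose(d[valid], 0.002, atol=1e-10)

    def test_first_order_annihilates_constants(self):
        d = sd.gap_segment_derivative(np.full(50, 9.0), self.GRID, GapSegParams(order=1))
        np.testing.assert_allclose(d[np.isfinite(d)], 0.0, atol=1e-12)

    def test_second_order_annihilates_linear(self):
        y = 1.0 + 0.3 * self.GRID.wavelengths_nm
        d = sd.gap_segment_derivative(y, self.GRID, GapSegParams(order=2))
        np.testing.assert_allclose(d[np.isfinite(d)], 0.0, atol=1e-10)

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_literal_segment_averaging_oracle(self, order):
        rng = np.random.default_rng(12)
        y = np.cumsum(rng.normal(size=50))  # random smooth-ish spectrum
        ours = sd.gap_segment_derivative(y, self.GRID, GapSegParams(order=order))
        theirs = gap_segment_oracle(y.tolist(), 1.0, order, 3, 2)
        np.testing.assert_allclose(ours, theirs, atol=1e-10, equal_nan=True)

    def test_edges_marked_invalid(self):
        d = sd.gap_segment_derivative(
            np.arange(50.0), self.GRID, GapSegParams(order=1)
        )
        assert np.isnan(d[:5]).all() and np.isnan(d[-5:]).all()
        assert np.isfinite(d[5:-5]).all()

    def test_non_uniform_grid_rejected(self):
        grid = sd.WavelengthGrid(np.array([1.0, 2.0, 4.0, 8.0, 16.0, 17, 18, 19, 20, 21, 22]))
        with pytest.raises(Exception, match="uniform"):
            sd.gap_segment_derivative(np.arange(11.0), grid, GapSegParams())

    def test_even_segment_rejected_for_second_order(self):
        with pytest.raises(ValueError, match="odd segment"):
            GapSegParams(order=2, segment=2)


# ------------------------------------------------------------------- peaks


def _profile(scores, start_nm=100.0):
    grid = sd.WavelengthGrid(start_nm + np.arange(len(scores), dtype=float))
    return ScoreProfile(grid=grid, scores=np.asarray(scores, float), method="entropy",
                        smoothed=True)


class TestDetectPeaks:
    def test_single_triangular_bump(self):
        scores = np.concatenate([np.arange(10.0), [10.0], np.arange(9.0, -1.0, -1)])
        peaks = sd.detect_peaks(_profile(scores), span=5)
        assert len(peaks) == 1
        assert peaks[0].wavelength_nm == 110.0

    def test_plateau_reports_lower_median_centre(self):
        scores = np.zeros(21)
        scores[0:10] = np.linspace(0, 0.9, 10)
        scores[10:15] = 1.0  # plateau at 110..114 nm
        scores[15:] = np.linspace(0.9, 0.0, 6)
        peaks = sd.detect_peaks(_profile(scores, start_nm=100.0), span=10)
        assert len(peaks) == 1
        assert peaks[0].wavelength_nm == 112.0

    def test_monotone_profile_has_no_peaks(self):
        assert sd.detect_peaks(_profile(np.arange(30.0)), span=5) == []
        assert sd.detect_peaks(_profile(np.arange(30.0, 0.0, -1.0)), span=5) == []

    def test_absolute_mode_finds_negative_extremum(self):
        scores = np.zeros(30)
        scores[14] = -5.0
        scores[13] = scores[15] = -2.0
        peaks = sd.detect_peaks(_profile(scores), span=5, use_absolute=True)
        assert peaks and peaks[0].wavelength_nm == 114.0

    def test_nan_positions_excluded(self):
        scores = np.zeros(30)
        scores[5] = np.nan
        scores[15] = 3.0
        scores[14] = scores[16] = 1.0
        peaks = sd.detect_peaks(_profile(scores), span=5)
        assert [p.wavelength_nm for p in peaks] == [115.0]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16), st.floats(-10, 10), st.floats(0.1, 10))
    def test_shift_and_positive_scale_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        base = [p.wavelength_nm for p in sd.detect_peaks(_profile(scores), span=6)]
        shifted = [
            p.wavelength_nm
            for p in sd.detect_peaks(_profile(scores * scale + shift), span=6)
        ]
        assert base == shifted


class TestTopK:
    def _bands(self, pairs):
        return [
            sd.SelectedBand(wavelength_nm=w, score=s, method="entropy")
            for w, s in pairs
        ]

    def test_selects_k_highest_reranked(self):
        bands = self._bands([(500 + i, float(i)) for i in range(9)])
        out = sd.top_k(bands, 5)
        assert [b.rank for b in out] == [1, 2, 3, 4, 5]
        scores = [b.score for b in out]
        assert scores == sorted(scores, reverse=True)

    def test_fewer_than_k_returns_all(self):
        out = sd.top_k(self._bands([(500, 1.0), (600, 2.0)]), 5)
        assert len(out) == 2

    def test_tie_breaks_to_lower_wavelength(self):
        out = sd.top_k(self._bands([(657, 1.0), (502, 1.0)]), 2)
        assert out[0].wavelength_nm == 502 and out[0].rank == 1


class TestSelectBands:
    def test_all_constant_spectra_empty_selection(self, tiny_set):
        s = sd.SpectraSet(
            grid=sd.WavelengthGrid(400.0 + np.arange(40.0)),
            reflectance=np.full((3, 40), 5.0),
            meta=tiny_set.meta,
        )
        table = sd.select_bands(s, method="infogain")
        assert table.empty

    def test_deterministic_across_repeated_runs(self, young_masked):
        a = sd.select_bands(young_masked, method="infogain")
        b = sd.select_bands(young_masked, method="infogain")
        assert a.equals(b)

    def test_smoothing_flag_set_by_profile_pipeline(self, young_masked):
        prof = smooth_profile(sd.entropy_profile(young_masked, "infogain"))
        assert prof.smoothed
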