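"""Histogram reduction: binning, permutation invariance, season truncation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yieldnet.histograms import (
    BinningScheme,
    CompositeFrame,
    CroplandMask,
    HistogramTensor,
    build_histogram_tensor,
    compute_bin_edges,
    default_composite_calendar,
    frame_histogram,
    month_day_to_doy,
    truncate_season,
)


def _frame(values, time_index=1, valid=None, loc="A", year=2004):
    return CompositeFrame(loc, year, time_index, np.asarray(values), valid)


def _full_mask(frame):
    return CroplandMask(frame.location_id, frame.year, np.ones(frame.bands.shape[:2], bool))


class TestBinEdges:
    def test_linear_edges_over_integer_range(self):
        vals = np.arange(32, dtype=float).reshape(4, 8, 1)
        scheme = compute_bin_edges([_frame(vals)], b=32)
        np.testing.assert_allclose(scheme.edges[0], np.arange(33) * 31 / 32)

    def test_unit_spacing_when_range_matches_bin_count(self):
        vals = np.arange(33, dtype=float).reshape(3, 11, 1)
        scheme = compute_bin_edges([_frame(vals)], b=32)
        np.testing.assert_allclose(scheme.edges[0], np.arange(33.0))

    def test_single_bin_gives_min_max(self):
        vals = np.array([[[0.2], [0.9]], [[0.5], [0.4]]])
        scheme = compute_bin_edges([_frame(vals)], b=1)
        np.testing.assert_allclose(scheme.edges, [[0.2, 0.9]])

    @pytest.mark.parametrize("b", [1, 3, 32])
    def test_edges_strictly_increasing_with_correct_length(self, rng, b):
        vals = rng.normal(size=(6, 6, 3))
        scheme = compute_bin_edges([_frame(vals)], b=b)
        assert scheme.edges.shape == (3, b + 1)
        assert (np.diff(scheme.edges, axis=1) > 0).all()

    def test_no_valid_pixels_is_an_error(self):
        frame = _frame(np.ones((2, 2, 1)), valid=np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="no valid pixels"):
            compute_bin_edges([frame], b=4)

    def test_nonfinite_pixels_are_an_error(self):
        vals = np.ones((2, 2, 1)) * np.inf
        with pytest.raises(ValueError, match="non-finite"):
            compute_bin_edges([_frame(vals, valid=np.ones((2, 2), bool))], b=4)

    def test_constant_band_still_yields_increasing_edges(self):
        scheme = compute_bin_edges([_frame(np.full((2, 2, 1), 5.0))], b=4)
        assert (np.diff(scheme.edges, axis=1) > 0).all()


class TestFrameHistogram:
    edges = BinningScheme(np.array([[0, 0.25, 0.5, 0.75, 1.0]]))

    def test_hand_counted_column(self):
        frame = _frame(np.array([0.1, 0.3, 0.3, 0.9]).reshape(1, 4, 1))
        h = frame_histogram(frame, _full_mask(frame), self.edges)
        np.testing.assert_allclose(h[:, 0], [0.25, 0.5, 0, 0.25])

    def test_point_mass_is_one_hot(self):
        frame = _frame(np.full((3, 3, 1), 0.6))
        h = frame_histogram(frame, _full_mask(frame), self.edges)
        np.testing.assert_array_equal(h[:, 0], [0, 0, 1, 0])

    def test_out_of_range_values_clamp_into_edge_bins(self):
        frame = _frame(np.array([-5.0, 5.0]).reshape(1, 2, 1))
        h = frame_histogram(
            frame, _full_mask(frame),
            BinningScheme(self.edges.edges, normalization="count"),
        )
        np.testing.assert_array_equal(h[:, 0], [1, 0, 0, 1])

    def test_last_bin_is_closed_at_the_top_edge(self):
        frame = _frame(np.array([1.0]).reshape(1, 1, 1))
        h = frame_histogram(frame, _full_mask(frame), self.edges)
        assert h[3, 0] == 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_spatial_permutation_leaves_histogram_bit_identical(self, seed):
        rng = np.random.default_rng(seed)
        bands = rng.random((6, 5, 2))
        valid = rng.random((6, 5)) < 0.9
        crop = rng.random((6, 5)) < 0.7
        scheme = BinningScheme(np.tile(np.linspace(0, 1, 9), (2, 1)))
        frame = _frame(bands, valid=valid)
        base = frame_histogram(frame, CroplandMask("A", 2004, crop), scheme)
        perm = rng.permutation(30)
        shuf = lambda a: a.reshape(30, -1)[perm].reshape(a.shape)
        frame2 = _frame(shuf(bands), valid=shuf(valid))
        shuffled = frame_histogram(frame2, CroplandMask("A", 2004, shuf(crop)), scheme)
        np.testing.assert_array_equal(base, shuffled)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_frequency_columns_sum_to_one_and_counts_conserve_mass(self, seed):
        rng = np.random.default_rng(seed)
        bands = rng.normal(size=(7, 4, 3))
        valid = rng.random((7, 4)) < 0.8
        crop = rng.random((7, 4)) < 0.8
        n = int((valid & crop).sum())
        edges = np.sort(rng.normal(size=(3, 6)), axis=1)
        edges += np.arange(6) * 1e-6  # enforce strictness under ties
        frame = _frame(bands, valid=valid)
        mask = CroplandMask("A", 2004, crop)
        freq = frame_histogram(frame, mask, BinningScheme(edges))
        count = frame_histogram(
            frame, mask, BinningScheme(edges, normalization="count")
        )
        expected = 1.0 if n else 0.0
        np.testing.assert_allclose(freq.sum(axis=0), expected, atol=1e-9)
        np.testing.assert_array_equal(count.sum(axis=0), n)

    def test_dimension_mismatch_is_an_error(self):
        frame = _frame(np.zeros((2, 2, 1)))
        with pytest.raises(ValueError, match="does not match"):
            frame_histogram(frame, CroplandMask("A", 2004, np.ones((3, 3), bool)), self.edges)

    def test_zero_counted_pixels_gives_zero_column_with_warning(self, caplog):
        frame = _frame(np.zeros((2, 2, 1)))
        mask = CroplandMask("A", 2004, np.zeros((2, 2), bool))
        with caplog.at_level("WARNING"):
            h = frame_histogram(frame, mask, self.edges)
        assert (h == 0).all()
        assert "no valid cropland pixels" in caplog.text


class TestHistogramTensor:
    def _frames(self, T, shape=(4, 4, 2), seed=0):
        rng = np.random.default_rng(seed)
        return [_frame(rng.random(shape), time_index=t) for t in range(1, T + 1)]

    def test_default_study_shape_is_30x32x9(self, rng):
        frames = [_frame(rng.random((3, 3, 9)), time_index=t) for t in range(1, 31)]
        scheme = BinningScheme(np.tile(np.linspace(0, 1, 33), (9, 1)))
        tensor = build_histogram_tensor(frames, _full_mask(frames[0]), scheme)
        assert tensor.shape == (30, 32, 9)

    def test_single_composite_keeps_leading_axis(self):
        frames = self._frames(1)
        scheme = BinningScheme(np.tile(np.linspace(0, 1, 5), (2, 1)))
        tensor = build_histogram_tensor(frames, _full_mask(frames[0]), scheme, n_composites=1)
        single = frame_histogram(frames[0], _full_mask(frames[0]), scheme)
        np.testing.assert_array_equal(tensor.values, single[None])

    def test_placement_is_keyed_by_time_index_not_order(self):
        frames = self._frames(5)
        scheme = BinningScheme(np.tile(np.linspace(0, 1, 5), (2, 1)))
        mask = _full_mask(frames[0])
        a = build_histogram_tensor(frames, mask, scheme, n_composites=5)
        b = build_histogram_tensor(frames[::-1], mask, scheme, n_composites=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_duplicate_time_index_is_an_error(self):
        frames = self._frames(2) + self._frames(1)
        scheme = BinningScheme(np.tile(np.linspace(0, 1, 5), (2, 1)))
        with pytest.raises(ValueError, match="duplicate time_index"):
            build_histogram_tensor(frames, _full_mask(frames[0]), scheme, n_composites=3)

    def test_missing_composites_become_zero_slices(self, caplog):
        frames = self._frames(2)
        scheme = BinningScheme(np.tile(np.linspace(0, 1, 5), (2, 1)))
        with caplog.at_level("WARNING"):
            tensor = build_histogram_tensor(frames, _full_mask(frames[0]), scheme, n_composites=4)
        assert (tensor.values[2:] == 0).all()
        assert "missing composites" in caplog.text


class TestTruncation:
    def _tensor(self, T=30):
        values = np.full((T, 4, 2), 1.0 / 4)
        return HistogramTensor(values, "A", 2004, T)

    def test_default_calendar_spans_march_to_october(self):
        cal = default_composite_calendar()
        assert (cal[1], cal[30]) == (65, 297)
        assert all(cal[t + 1] - cal[t] == 8 for t in range(1, 30))

    @pytest.mark.parametrize(
        "month,day,expected_cutoff",
        [(7, 23, 18), (8, 23, 22), (9, 23, 26), (10, 23, 29)],
    )
    def test_forecast_date_cutoffs(self, month, day, expected_cutoff):
        out = truncate_season(self._tensor(), month_day_to_doy(month, day))
        assert out.cutoff_index == expected_cutoff
        assert (out.values[expected_cutoff:] == 0).all()
        assert (out.values[:expected_cutoff] > 0).all()

    def test_forecast_after_season_is_identity(self):
        t = self._tensor()
        out = truncate_season(t, 365)
        np.testing.assert_array_equal(out.values, t.values)
        assert out.cutoff_index == 30

    def test_forecast_before_season_zeroes_everything(self):
        out = truncate_season(self._tensor(), 10)
        assert out.cutoff_index == 0
        assert (out.values == 0).all()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 366), st.integers(1, 366))
    def test_idempotent_and_monotone(self, doy_a, doy_b):
        t = self._tensor()
        once = truncate_season(t, doy_a)
        twice = truncate_season(once, doy_a)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.cutoff_index == twice.cutoff_index
        lo, hi = sorted((doy_a, doy_b))
        assert (
            truncate_season(t, lo).cutoff_index <= truncate_season(t, hi).cutoff_index
        )

    def test_incomplete_calendar_is_an_error(self):
        with pytest.raises(ValueError, match="does not cover"):
            truncate_season(self._tensor(), 200, {1: 65})
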