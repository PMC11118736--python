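"""Slice I/O, normalizations, windowing and polygon-mask rasterization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image
from shapely.geometry import Point, Polygon

from lungfat.imaging_io import (
    CTSlice,
    DegenerateSliceError,
    FormatError,
    LocalizationLabel,
    SliceWindow,
    make_windows,
    max_intensity_norm,
    max_min_norm,
    rasterize_polygons,
    read_label_csv,
    read_mask_labels,
    read_slice,
    write_label_csv,
    write_slice,
)


def _slice(pixels, spacing=2.5, index=0):
    return CTSlice(pixels=np.asarray(pixels), spacing_mm=spacing, index=index)


class TestSliceIO:
    def test_write_read_round_trip_is_pixel_identical(self, tmp_path, rng):
        pixels = rng.integers(0, 65536, size=(32, 32))
        path = tmp_path / "s.png"
        write_slice(_slice(pixels), path)
        back = read_slice(path, spacing_mm=2.5, index=4)
        assert np.array_equal(back.pixels, pixels)
        assert back.spacing_mm == 2.5 and back.index == 4

    def test_sixteen_bit_values_survive(self, tmp_path):
        pixels = np.array([[0, 4095], [4096, 65535]])
        path = tmp_path / "s.png"
        write_slice(_slice(pixels), path)
        assert np.array_equal(read_slice(path, 1.0).pixels, pixels)

    def test_rgb_png_rejected_naming_channel_count(self, tmp_path):
        path = tmp_path / "rgb.png"
        Image.new("RGB", (8, 8)).save(path)
        with pytest.raises(FormatError, match="3 channels"):
            read_slice(path, 1.0)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_slice(tmp_path / "absent.png", 1.0)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            _slice(np.zeros((4, 4), dtype=int), spacing=0.0)

    def test_negative_pixels_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _slice(np.array([[-1, 0], [0, 0]]))


class TestNormalizations:
    def test_max_intensity_fixed_points(self):
        out = max_intensity_norm(_slice(np.array([[0, 4095], [8190, 2047]])))
        assert out[0, 0] == 0.0
        assert out[0, 1] == 1.0
        assert out[1, 0] == 1.0  # above-ceiling values clip after division

    def test_max_intensity_linear_below_ceiling(self, rng):
        a = rng.integers(0, 2000, size=(8, 8))
        b = rng.integers(0, 2000, size=(8, 8))
        np.testing.assert_allclose(
            max_intensity_norm(_slice(a)) + max_intensity_norm(_slice(b)),
            max_intensity_norm(_slice(a + b)),
            atol=1e-12,
        )

    def test_max_min_norm_example(self):
        out = max_min_norm(_slice(np.array([[0, 50, 100]])))
        np.testing.assert_allclose(out, [[0.0, 0.5, 1.0]])

    def test_constant_slice_is_degenerate_and_names_index(self):
        with pytest.raises(DegenerateSliceError, match="slice 7"):
            max_min_norm(_slice(np.full((4, 4), 7), index=7))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_max_min_norm_attains_zero_and_one(self, seed):
        r = np.random.default_rng(seed)
        arr = r.integers(0, 4096, size=(16, 16))
        if arr.min() == arr.max():
            arr[0, 0] += 1
        out = max_min_norm(_slice(arr))
        assert out.min() == 0.0 and out.max() == 1.0


class TestWindows:
    def _volume(self, n):
        return [_slice(np.full((8, 8), i), index=i) for i in range(n)]

    def test_ten_slices_l5_gives_six_center_labelled_windows(self):
        labels = [1] * 10
        labels[4] = 0
        windows = make_windows(self._volume(10), labels, 5)
        assert len(windows) == 6
        assert [w.center_index for w in windows] == [2, 3, 4, 5, 6, 7]
        assert windows[2].label == LocalizationLabel.FIRST

    def test_exact_length_volume_gives_single_window(self):
        assert len(make_windows(self._volume(5), [1] * 5, 5)) == 1

    def test_short_volume_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            make_windows(self._volume(3), [1] * 3, 5)

    def test_even_or_large_window_length_rejected(self):
        with pytest.raises(ValueError, match="3, 5, 7"):
            make_windows(self._volume(10), [1] * 10, 9)

    @settings(max_examples=60, deadline=None)
    @given(st.sampled_from([3, 5, 7]), st.integers(0, 30))
    def test_window_count_is_n_minus_l_plus_one(self, L, extra):
        n = L + extra
        windows = make_windows(self._volume(n), [1] * n, L)
        assert len(windows) == n - L + 1

    def test_window_invariants_enforced(self):
        vol = self._volume(5)
        vol[2] = _slice(np.zeros((8, 8), dtype=int), index=4)  # gap in indices
        with pytest.raises(ValueError, match="consecutive"):
            SliceWindow(slices=vol, label=LocalizationLabel.OTHER)

    def test_onehot_encoding_marks_single_position(self):
        for lab in LocalizationLabel:
            v = lab.onehot
            assert v.sum() == 1 and v[int(lab)] == 1


class TestPolygonMasks:
    def test_square_polygon_matches_point_in_polygon_scan(self):
        poly = [[10, 10], [20, 10], [20, 20], [10, 20]]
        mask = rasterize_polygons([poly], (64, 64))
        shp = Polygon(poly)
        expected = np.zeros((64, 64), dtype=np.uint8)
        for r in range(64):
            for c in range(64):
                expected[r, c] = shp.contains(Point(c + 0.5, r + 0.5))
        assert np.array_equal(mask, expected)
        assert mask.sum() == 100  # 10x10 pixels strictly inside corner coords

    def test_empty_polygon_list_gives_zero_mask(self):
        assert rasterize_polygons([], (16, 16)).sum() == 0

    def test_out_of_bounds_vertex_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rasterize_polygons([[[700, 10], [10, 10], [10, 20]]], (512, 512))

    def test_hole_via_even_odd_rule(self):
        outer = [[2, 2], [14, 2], [14, 14], [2, 14]]
        inner = [[6, 6], [10, 6], [10, 10], [6, 10]]
        mask = rasterize_polygons([outer, inner], (16, 16))
        assert mask[8, 8] == 0 and mask[3, 3] == 1
        assert mask.sum() == 12 * 12 - 4 * 4

    def test_read_mask_labels_json(self, tmp_path):
        doc = {"tissue": "SAT", "polygons": [[[1, 1], [4, 1], [4, 4], [1, 4]]]}
        p = tmp_path / "m.json"
        p.write_text(json.dumps(doc))
        mask = read_mask_labels(p, (8, 8))
        assert mask.sum() == 9

    def test_malformed_json_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_mask_labels(p, (8, 8))


class TestSegSample:
    def test_valid_sample_and_contract_violations(self, rng):
        from lungfat.imaging_io import SegSample

        img = _slice(rng.integers(0, 4096, size=(8, 8)))
        mask = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
        sample = SegSample(image=img, mask=mask, tissue="VAT")
        assert sample.mask.shape == img.pixels.shape
        with pytest.raises(ValueError, match="shape"):
            SegSample(image=img, mask=np.zeros((4, 4), dtype=np.uint8), tissue="SAT")
        with pytest.raises(ValueError, match="binary"):
            SegSample(image=img, mask=np.full((8, 8), 2), tissue="SAT")
        with pytest.raises(ValueError, match="tissue"):
            SegSample(image=img, mask=mask, tissue="BONE")


class TestLabelCSV:
    def test_round_trip(self, tmp_path):
        labels = [LocalizationLabel.OTHER] * 6
        labels[2] = LocalizationLabel.FIRST
        labels[4] = LocalizationLabel.LAST
        p = tmp_path / "labels.csv"
        write_label_csv(labels, p)
        assert read_label_csv(p) == labels
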