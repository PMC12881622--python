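"""Raster core: I/O round-trips, bilinear resampling, masking, compositing."""

import datetime
import itertools

import numpy as np
import pytest

from forestchange import grids
from forestchange.errors import EmptyMosaicError, FormatError, ParameterError

from conftest import constant_stack


class TestRasterIO:
    def test_roundtrip_preserves_values_mask_and_metadata(self, tmp_path):
        rng = np.random.default_rng(0)
        bands = rng.uniform(0, 1, size=(10, 6, 7)).astype(np.float32)
        valid = rng.uniform(size=(6, 7)) > 0.3
        stack = grids.BandStack(
            bands=bands, valid_mask=valid, pixel_size=10.0,
            transform=grids.Affine.scale(10.0), date=datetime.date(2020, 6, 15),
        )
        path = tmp_path / "stack.tif"
        grids.write_raster(stack, path)
        back = grids.read_raster(path)
        np.testing.assert_array_equal(back.valid_mask, valid)
        np.testing.assert_allclose(back.bands[:, valid], bands[:, valid])
        assert back.date == stack.date
        assert back.transform == stack.transform

    def test_nine_band_file_is_a_format_error(self, tmp_path):
        import json

        import tifffile

        path = tmp_path / "bad.tif"
        tifffile.imwrite(
            path,
            np.zeros((9, 4, 4), dtype=np.float32),
            photometric="minisblack",
            description=json.dumps({"band_names": list(grids.BAND_NAMES[:9])}),
        )
        with pytest.raises(FormatError):
            grids.read_raster(path)

    def test_label_raster_roundtrip_with_code_table(self, tmp_path):
        labels = grids.LabelRaster(
            labels=np.array([[1, 2], [0, 8]]), code_table={1: "coniferous", 8: "water"}
        )
        path = tmp_path / "labels.tif"
        grids.write_labels(labels, path)
        back = grids.read_labels(path)
        np.testing.assert_array_equal(back.labels, labels.labels)
        assert back.code_table == labels.code_table


def brute_force_bilinear(src, ratio, r, c):
    """Independent bilinear evaluation at target centre (r, c)."""
    fr = (r + 0.5) / ratio - 0.5
    fc = (c + 0.5) / ratio - 0.5
    fr = min(max(fr, 0.0), src.shape[0] - 1)
    fc = min(max(fc, 0.0), src.shape[1] - 1)
    r0, c0 = int(np.floor(fr)), int(np.floor(fc))
    r1, c1 = min(r0 + 1, src.shape[0] - 1), min(c0 + 1, src.shape[1] - 1)
    wr, wc = fr - r0, fc - c0
    return (
        src[r0, c0] * (1 - wr) * (1 - wc)
        + src[r0, c1] * (1 - wr) * wc
        + src[r1, c0] * wr * (1 - wc)
        + src[r1, c1] * wr * wc
    )


class TestResampleBilinear:
    def test_constant_field_stays_constant(self):
        out = grids.resample_bilinear(np.full((5, 5), 0.3), 20.0, 10.0)
        assert out.shape == (10, 10)
        np.testing.assert_allclose(out, 0.3)

    def test_monotone_in_column_for_column_gradient(self):
        out = grids.resample_bilinear(np.array([[0.0, 1.0], [0.0, 1.0]]), 20.0, 10.0)
        assert (np.diff(out, axis=1) >= 0).all()
        np.testing.assert_allclose(out[0], out[-1])

    def test_checkerboard_matches_brute_force_and_stays_in_range(self):
        rng = np.random.default_rng(3)
        src = (np.indices((6, 6)).sum(axis=0) % 2).astype(float)
        src += rng.uniform(0, 0.1, size=src.shape)
        out = grids.resample_bilinear(src, 20.0, 10.0)
        assert out.min() >= src.min() - 1e-12 and out.max() <= src.max() + 1e-12
        for r, c in itertools.product(range(0, 12, 3), range(0, 12, 3)):
            assert out[r, c] == pytest.approx(brute_force_bilinear(src, 2, r, c))

    def test_non_commensurate_grids_rejected(self):
        with pytest.raises(ParameterError):
            grids.resample_bilinear(np.zeros((4, 4)), 25.0, 10.0)


class TestCloudMask:
    def test_zero_probability_and_clear_scl_change_nothing(self):
        stack = constant_stack([0.2] * 10)
        out = grids.apply_cloud_mask(
            stack, np.zeros(stack.shape), np.full(stack.shape, 4)
        )
        np.testing.assert_array_equal(out.valid_mask, stack.valid_mask)
        np.testing.assert_array_equal(out.bands, stack.bands)

    def test_probability_one_invalidates_everything(self):
        stack = constant_stack([0.2] * 10)
        out = grids.apply_cloud_mask(
            stack, np.ones(stack.shape), np.full(stack.shape, 4)
        )
        assert not out.valid_mask.any()

    def test_shadow_codes_alone_remove_exactly_the_coded_pixels(self):
        stack = constant_stack([0.2] * 10)
        scl = np.full(stack.shape, 4)
        scl[1, 2] = 3
        scl[4, 5] = 9
        out = grids.apply_cloud_mask(stack, np.zeros(stack.shape), scl)
        expected = ~np.isin(scl, [3, 9])
        np.testing.assert_array_equal(out.valid_mask, expected)

    def test_shape_mismatch_rejected(self):
        stack = constant_stack([0.2] * 10)
        with pytest.raises(ParameterError):
            grids.apply_cloud_mask(stack, np.zeros((3, 3)), np.zeros((3, 3)))


class TestSeasonalMedianMosaic:
    def _stacks(self, values_by_date, masks=None):
        out = []
        for i, v in enumerate(values_by_date):
            date = datetime.date(2020, 6 + i % 3, 10)
            valid = None if masks is None else masks[i]
            out.append(constant_stack([v] * 10, date=date, valid=valid))
        return out

    def test_odd_count_median(self):
        mosaic = grids.seasonal_median_mosaic(self._stacks([0.2, 0.9, 0.4]))
        np.testing.assert_allclose(mosaic.bands, 0.4)
        assert (mosaic.count == 3).all()

    def test_constant_series_is_idempotent(self):
        mosaic = grids.seasonal_median_mosaic(self._stacks([0.3, 0.3, 0.3]))
        np.testing.assert_allclose(mosaic.bands, 0.3)

    def test_even_count_median_is_mean_of_middle_two(self):
        shape = (8, 8)
        masks = [np.ones(shape, bool), np.ones(shape, bool), np.zeros(shape, bool)]
        mosaic = grids.seasonal_median_mosaic(self._stacks([0.2, 0.9, 0.4], masks))
        np.testing.assert_allclose(mosaic.bands, (0.2 + 0.9) / 2)
        assert (mosaic.count == 2).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        stacks = []
        for i in range(4):
            bands = rng.uniform(0, 1, size=(10, 5, 5)).astype(np.float32)
            valid = rng.uniform(size=(5, 5)) > 0.2
            stacks.append(
                grids.BandStack(bands=bands, valid_mask=valid,
                                date=datetime.date(2020, 6 + i % 3, 5 + i))
            )
        a = grids.seasonal_median_mosaic(stacks)
        b = grids.seasonal_median_mosaic(stacks[::-1])
        np.testing.assert_array_equal(a.count, b.count)
        np.testing.assert_array_equal(a.bands, b.bands)

    def test_window_excludes_out_of_season_dates(self):
        stacks = self._stacks([0.2, 0.9, 0.4])
        stacks.append(constant_stack([0.99] * 10, date=datetime.date(2020, 4, 1)))
        mosaic = grids.seasonal_median_mosaic(stacks, window=(6, 8))
        np.testing.assert_allclose(mosaic.bands, 0.4)

    def test_empty_window_raises(self):
        stacks = self._stacks([0.2])
        with pytest.raises(EmptyMosaicError):
            grids.seasonal_median_mosaic(stacks, window=(1, 2))

    def test_masking_never_changes_untouched_pixels(self):
        rng = np.random.default_rng(1)
        stacks = []
        for i in range(3):
            bands = rng.uniform(0, 1, size=(10, 6, 6)).astype(np.float32)
            stacks.append(grids.BandStack(
                bands=bands, valid_mask=np.ones((6, 6), bool),
                date=datetime.date(2020, 6 + i, 10)))
        full = grids.seasonal_median_mosaic(stacks)
        masked = [s.copy() for s in stacks]
        masked[0].valid_mask[:3, :] = False
        partial = grids.seasonal_median_mosaic(masked)
        assert (partial.count <= full.count).all()
        untouched = partial.count == full.count
        np.testing.assert_array_equal(
            partial.bands[:, untouched], full.bands[:, untouched]
        )


class TestGapFill:
    def test_holes_take_mosaic_values_and_validity_grows(self):
        stack = constant_stack([0.2] * 10)
        stack.valid_mask[0, 0] = False
        mosaic = grids.seasonal_median_mosaic(
            [constant_stack([0.5] * 10, date=datetime.date(2020, 7, 1))]
        )
        filled = grids.gap_fill(stack, mosaic)
        assert filled.valid_mask.all()
        assert filled.bands[0, 0, 0] == pytest.approx(0.5)
        assert filled.bands[0, 1, 1] == pytest.approx(0.2)
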