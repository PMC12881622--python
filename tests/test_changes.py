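"""Change detection: feature stack, reference sampling, classification, MMU."""

import numpy as np
import pytest
import shapely

from forestchange import changes as chg
from forestchange import classify as cls
from forestchange import grids, indices
from forestchange.errors import ParameterError, SamplingError

from conftest import noiseless_signatures  # noqa: F401  (used via fixtures)


def build_stack_pair(acquisitions, truth, forest_from_truth=True):
    """Mosaics, differences, feature stack and forest mask for a 2-year scene."""
    m1 = grids.seasonal_median_mosaic(acquisitions[2020], (6, 8), year=2020)
    m2 = grids.seasonal_median_mosaic(acquisitions[2021], (6, 8), year=2021)
    woody = np.isin(truth.truth_labels[2020].labels, [1, 2])
    fmask = cls.ForestMask(mask=woody, pixel_size=m1.pixel_size, transform=m1.transform)
    dndvi = indices.index_difference(indices.ndvi(m1), indices.ndvi(m2), domain=woody)
    dnbr = indices.index_difference(indices.nbr(m1), indices.nbr(m2), domain=woody)
    stack = chg.build_feature_stack(m1, m2, dndvi, dnbr, fmask)
    return m1, m2, dndvi, dnbr, stack, fmask


class TestFeatureStack:
    def test_feature_count_is_twenty_two(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        *_, stack, _ = build_stack_pair(acquisitions, truth)
        assert stack.features.shape[0] == 22
        assert len(stack.schema) == 22

    def test_pixel_invalid_in_second_mosaic_is_invalid_in_stack(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        m1, m2, dndvi, dnbr, _, fmask = build_stack_pair(acquisitions, truth)
        m2.count[3, 4] = 0
        stack = chg.build_feature_stack(m1, m2, dndvi, dnbr, fmask)
        assert not stack.valid_mask[3, 4]

    def test_unchanged_pixels_have_zero_difference_features(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        *_, stack, _ = build_stack_pair(acquisitions, truth)
        change = truth.truth_change[(2020, 2021)].classes
        untouched = (change == chg.CHANGE_NO) & stack.valid_mask
        d_ndvi = stack.features[20][untouched]
        d_nbr = stack.features[21][untouched]
        assert np.abs(d_ndvi).max() < 1e-6 and np.abs(d_nbr).max() < 1e-6

    def test_year_mismatch_rejected(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        m1, m2, dndvi, dnbr, _, fmask = build_stack_pair(acquisitions, truth)
        bad = indices.DifferenceRaster(
            values=dndvi.values, index_name="dNDVI", years=(2021, 2022),
            mean=0.0, sd=0.0,
        )
        with pytest.raises(ParameterError):
            chg.build_feature_stack(m1, m2, bad, dnbr, fmask)


class TestReferenceAreas:
    def test_seven_three_split_per_class(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        *_, stack, _ = build_stack_pair(acquisitions, truth)
        areas = chg.reference_areas_from_truth(
            truth.truth_change[(2020, 2021)], rng_seed=0
        )
        samples = chg.sample_reference_areas(areas, stack, per_class_n=10, rng_seed=0)
        for code in chg.CHANGE_CLASSES:
            sub = samples.frame[samples.frame["land_cover"] == code]
            assert (sub["role"] == "train").sum() == 7
            assert (sub["role"] == "validation").sum() == 3

    def test_points_lie_inside_their_polygons(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        *_, stack, _ = build_stack_pair(acquisitions, truth)
        areas = chg.reference_areas_from_truth(
            truth.truth_change[(2020, 2021)], rng_seed=0
        )
        samples = chg.sample_reference_areas(areas, stack, per_class_n=8, rng_seed=1)
        for _, row in samples.frame.iterrows():
            polys = [a.polygon for a in areas if a.change_class == row["land_cover"]]
            assert any(shapely.contains_xy(p, row["x"], row["y"]) for p in polys)

    def test_missing_class_is_a_sampling_error(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        *_, stack, _ = build_stack_pair(acquisitions, truth)
        areas = [
            a
            for a in chg.reference_areas_from_truth(
                truth.truth_change[(2020, 2021)], rng_seed=0
            )
            if a.change_class != chg.CHANGE_BURNT
        ]
        with pytest.raises(SamplingError):
            chg.sample_reference_areas(areas, stack, per_class_n=5, rng_seed=0)

    def test_out_of_range_area_warns(self):
        with pytest.warns(UserWarning):
            chg.ReferenceArea(polygon=shapely.box(0, 0, 50, 50), change_class=1)


class TestChangeClassification:
    def _model_and_stack(self, acquisitions, truth, seed=0):
        *_, stack, fmask = build_stack_pair(acquisitions, truth)
        areas = chg.reference_areas_from_truth(
            truth.truth_change[(2020, 2021)], rng_seed=seed
        )
        samples = chg.sample_reference_areas(areas, stack, per_class_n=15, rng_seed=seed)
        model = chg.train_change_model(samples, stack, rng_seed=seed)
        return model, stack, fmask

    def test_noise_free_pair_recovers_truth_exactly(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        model, stack, fmask = self._model_and_stack(acquisitions, truth)
        cmap = chg.classify_changes(stack, model, fmask)
        expected = truth.truth_change[(2020, 2021)].classes
        np.testing.assert_array_equal(cmap.classes, expected)

    def test_transfer_to_identical_years_says_no_change(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        model, _, fmask = self._model_and_stack(acquisitions, truth)
        m = grids.seasonal_median_mosaic(acquisitions[2020], (6, 8), year=2020)
        m_next = grids.seasonal_median_mosaic(acquisitions[2020], (6, 8), year=2020)
        m_next.year = 2021
        dndvi = indices.index_difference(
            indices.ndvi(m), indices.ndvi(m_next), domain=fmask.mask
        )
        dnbr = indices.index_difference(
            indices.nbr(m), indices.nbr(m_next), domain=fmask.mask
        )
        stack = chg.build_feature_stack(m, m_next, dndvi, dnbr, fmask)
        cmap = chg.classify_changes(stack, model, fmask)
        assert (cmap.classes[stack.valid_mask] == chg.CHANGE_NO).all()

    def test_pixels_outside_forest_mask_are_class_zero(self, noise_free_scene):
        _, acquisitions, truth = noise_free_scene
        model, stack, fmask = self._model_and_stack(acquisitions, truth)
        cmap = chg.classify_changes(stack, model, fmask)
        assert (cmap.classes[~fmask.mask] == chg.CHANGE_OUTSIDE).all()


def flood_fill_components(binary, connectivity=2):
    """Independent component areas by explicit flood fill."""
    seen = np.zeros_like(binary, dtype=bool)
    if connectivity == 2:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    sizes = {}
    for r0 in range(binary.shape[0]):
        for c0 in range(binary.shape[1]):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            stack, members = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                members.append((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < binary.shape[0] and 0 <= cc < binary.shape[1]
                            and binary[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            for m in members:
                sizes[m] = len(members)
    return sizes


def make_change_map(classes):
    return chg.ChangeMap(classes=np.asarray(classes, dtype=np.int16), years=(2020, 2021))


class TestMmuFilter:
    def test_four_pixel_patch_removed_five_kept(self):
        grid = np.ones((10, 10), dtype=np.int16)
        grid[1, 1:5] = 2            # 4 pixels = 400 m² -> removed
        grid[5, 1:6] = 3            # 5 pixels = 500 m² -> kept
        out = chg.mmu_filter(make_change_map(grid))
        assert (out.classes != 2).all()
        assert (out.classes == 3).sum() == 5

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(0)
        grid = rng.choice([1, 2, 3], size=(30, 30), p=[0.9, 0.05, 0.05]).astype(np.int16)
        once = chg.mmu_filter(make_change_map(grid))
        twice = chg.mmu_filter(once)
        np.testing.assert_array_equal(once.classes, twice.classes)

    @pytest.mark.parametrize("seed", range(4))
    def test_decisions_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.choice([0, 1, 2, 3], size=(40, 40), p=[0.1, 0.7, 0.1, 0.1]).astype(np.int16)
        out = chg.mmu_filter(make_change_map(grid))
        for cls_code in (2, 3):
            sizes = flood_fill_components(grid == cls_code)
            for (r, c), size in sizes.items():
                if size <= 4:
                    assert out.classes[r, c] == 1, (r, c, size)
                else:
                    assert out.classes[r, c] == cls_code, (r, c, size)

    def test_diagonal_fragments_count_as_one_component(self):
        grid = np.ones((8, 8), dtype=np.int16)
        for i in range(5):              # 5-pixel diagonal: one 8-connected component
            grid[i, i] = 2
        out = chg.mmu_filter(make_change_map(grid))
        assert (out.classes == 2).sum() == 5
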