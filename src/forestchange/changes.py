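"""Direct classification of forest change within the year-1 forest mask.

A 22-feature stack (10 bands of each annual mosaic plus dNDVI and dNBR) is
classified by a 100-tree random forest into {no change, woody converted to
non-woody, burnt forest}.  Reference points come from labelled polygons
("reference areas"), split 7:3 into training and validation.  The fitted
model transfers unchanged to other scenes and year pairs.  A minimum-mapping-
unit filter removes change patches of 400 m² or less (4 pixels at 10 m).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from skimage import measure

from .classify import ClassifierModel, FeatureTable, ForestMask, train_model
from .errors import ParameterError, SamplingError
from .grids import Affine, AnnualMosaic
from .indices import DifferenceRaster
from .sampling import SampleSet, split_samples

logger = logging.getLogger(__name__)

#: Change-map codes, fixed across the package and written to code-table sidecars.
CHANGE_OUTSIDE, CHANGE_NO, CHANGE_WOODY, CHANGE_BURNT = 0, 1, 2, 3
CHANGE_CODE_TABLE = {
    CHANGE_OUTSIDE: "outside forest mask / invalid",
    CHANGE_NO: "no change",
    CHANGE_WOODY: "woody to non-woody",
    CHANGE_BURNT: "burnt forest",
}
CHANGE_CLASSES = (CHANGE_NO, CHANGE_WOODY, CHANGE_BURNT)


@dataclass
class ChangeMap:
    """Categorical change grid for one year pair."""

    classes: np.ndarray
    years: tuple[int, int]
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))
    mmu_applied: bool = False
    code_table: dict[int, str] = field(default_factory=lambda: dict(CHANGE_CODE_TABLE))

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


@dataclass
class ChangeFeatureStack:
    """Per-pixel 22-feature stack: two mosaics' bands plus dNDVI and dNBR."""

    features: np.ndarray          # (22, rows, cols)
    valid_mask: np.ndarray
    schema: tuple[str, ...]
    years: tuple[int, int]
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.features.shape[1:]

    def features_at(self, rows, cols) -> np.ndarray:
        return self.features[:, np.asarray(rows), np.asarray(cols)].T


@dataclass
class ReferenceArea:
    """A manually delineated polygon of known change class."""

    polygon: shapely.Geometry
    change_class: int
    pixel_size: float = 10.0

    def __post_init__(self) -> None:
        if self.change_class not in CHANGE_CLASSES:
            raise ParameterError(f"reference class must be one of {CHANGE_CLASSES}")
        if not (4.0 <= self.area_ha <= 400.0):
            warnings.warn(
                f"reference area of {self.area_ha:.2f} ha outside the expected "
                "4-400 ha range",
                stacklevel=2,
            )

    @property
    def area_ha(self) -> float:
        return self.polygon.area / 1e4


def build_feature_stack(
    mosaic_t1: AnnualMosaic,
    mosaic_t2: AnnualMosaic,
    dndvi: DifferenceRaster,
    dnbr: DifferenceRaster,
    forest_mask: ForestMask,
) -> ChangeFeatureStack:
    """Stack the 22 change features; valid only where every input is valid in-mask."""
    years = (mosaic_t1.year, mosaic_t2.year)
    for diff in (dndvi, dnbr):
        if diff.years != years:
            raise ParameterError(
                f"difference years {diff.years} do not match mosaics {years}"
            )
    shape = mosaic_t1.shape
    for grid in (mosaic_t2.bands[0], dndvi.values, dnbr.values, forest_mask.mask):
        if grid.shape != shape:
            raise ParameterError("change-feature inputs are not co-registered")
    schema = tuple(
        [f"t1_{b}" for b in mosaic_t1.band_names]
        + [f"t2_{b}" for b in mosaic_t2.band_names]
        + ["dNDVI", "dNBR"]
    )
    features = np.concatenate(
        [
            mosaic_t1.bands.astype(np.float32),
            mosaic_t2.bands.astype(np.float32),
            dndvi.values[None].astype(np.float32),
            dnbr.values[None].astype(np.float32),
        ]
    )
    valid = (
        mosaic_t1.valid_mask
        & mosaic_t2.valid_mask
        & np.isfinite(dndvi.values)
        & np.isfinite(dnbr.values)
        & forest_mask.mask
    )
    return ChangeFeatureStack(
        features=features,
        valid_mask=valid,
        schema=schema,
        years=years,
        pixel_size=mosaic_t1.pixel_size,
        transform=mosaic_t1.transform,
    )


def sample_reference_areas(
    areas: list[ReferenceArea],
    stack: ChangeFeatureStack,
    per_class_n: int = 100,
    rng_seed: int = 0,
    train_fraction: float = 0.7,
) -> SampleSet:
    """Stratified random points inside the reference polygons, split 7:3.

    All three change classes must be covered by at least one polygon; points
    land only on valid stack pixels whose centre lies inside a polygon of the
    class.  Deterministic given the seed.
    """
    present = {a.change_class for a in areas}
    missing = set(CHANGE_CLASSES) - present
    if missing:
        raise SamplingError(
            f"reference areas must cover all change classes; missing {sorted(missing)}"
        )
    from .geometry import polygon_pixel_mask  # local import avoids a cycle

    rng = np.random.default_rng(rng_seed)
    rows_out, cols_out, codes_out = [], [], []
    for cls in CHANGE_CLASSES:
        mask = np.zeros(stack.shape, dtype=bool)
        for area in areas:
            if area.change_class == cls:
                mask |= polygon_pixel_mask(area.polygon, stack.shape, stack.transform)
        mask &= stack.valid_mask
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            raise SamplingError(f"no valid pixels inside reference areas of class {cls}")
        n = min(per_class_n, rr.size)
        if n < per_class_n:
            logger.warning("class %d: only %d valid pixels for %d requested points",
                           cls, rr.size, per_class_n)
        pick = rng.choice(rr.size, size=n, replace=False)
        rows_out.extend(rr[pick].tolist())
        cols_out.extend(cc[pick].tolist())
        codes_out.extend([cls] * n)
    rows_arr = np.asarray(rows_out)
    cols_arr = np.asarray(cols_out)
    x, y = stack.transform.xy(rows_arr, cols_arr)
    frame = pd.DataFrame(
        {
            "row": rows_arr, "col": cols_arr, "x": x, "y": y,
            "land_cover": codes_out,
            "forest_flag": "forest",      # change samples lie inside the forest mask
            "leaf_type": "none",
            "role": "unassigned",
            "source": "change-reference-area",
        }
    )
    samples = SampleSet(frame, provenance={"per_class_n": per_class_n, "rng_seed": rng_seed})
    return split_samples(samples, train_fraction, rng_seed)


def change_feature_table(samples: SampleSet, stack: ChangeFeatureStack,
                         role: str | None = "train") -> FeatureTable:
    """Feature table for change samples (optionally restricted to one role)."""
    frame = samples.frame
    if role is not None:
        frame = frame[frame["role"] == role]
    X = pd.DataFrame(
        stack.features_at(frame["row"].to_numpy(), frame["col"].to_numpy()),
        columns=list(stack.schema),
    )
    y = frame["land_cover"].reset_index(drop=True)
    return FeatureTable(X=X, y=y, task="change", schema=stack.schema)


def train_change_model(
    samples: SampleSet,
    stack: ChangeFeatureStack,
    n_trees: int = 100,
    rng_seed: int = 0,
) -> ClassifierModel:
    """Fit the 100-tree change classifier on the training-role samples."""
    table = change_feature_table(samples, stack, role="train")
    present = set(np.unique(table.y))
    if not set(CHANGE_CLASSES) <= present:
        raise SamplingError(
            f"training samples must cover classes {CHANGE_CLASSES}, got {sorted(present)}"
        )
    return train_model(table, task="change", n_trees=n_trees, rng_seed=rng_seed)


def classify_changes(
    stack: ChangeFeatureStack,
    model: ClassifierModel,
    forest_mask: ForestMask,
) -> ChangeMap:
    """Label every valid in-mask pixel; everything else becomes class 0.

    Transfer across scenes or periods is exactly this call with a model
    fitted elsewhere — schema compatibility is enforced.
    """
    domain = stack.valid_mask & forest_mask.mask
    flat = domain.ravel()
    pred = np.zeros(flat.size, dtype=np.int16)
    if flat.any():
        X = stack.features.reshape(len(stack.schema), -1).T
        pred[flat] = model.predict(X[flat], stack.schema)
    return ChangeMap(
        classes=pred.reshape(stack.shape),
        years=stack.years,
        pixel_size=stack.pixel_size,
        transform=stack.transform,
    )


def reference_areas_from_truth(
    truth_change: ChangeMap,
    erosion_px: int = 1,
    no_change_patch_px: int = 20,
    rng_seed: int = 0,
) -> list[ReferenceArea]:
    """Derive reference polygons from a labelled change map.

    Each connected change component contributes its bounding box shrunk by
    ``erosion_px`` pixels on every side (keeps points off component edges);
    one all-no-change rectangle of up to ``no_change_patch_px`` pixels a side
    is searched for the no-change class.  Stands in for the manual image-
    interpreted delineation used with real scenes.
    """
    px = truth_change.pixel_size
    rng = np.random.default_rng(rng_seed)
    areas: list[ReferenceArea] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # synthetic patches are below 4 ha
        for cls in (CHANGE_WOODY, CHANGE_BURNT):
            comp = measure.label(truth_change.classes == cls, connectivity=2)
            for region in measure.regionprops(comp):
                r0, c0, r1, c1 = region.bbox
                r0, c0 = r0 + erosion_px, c0 + erosion_px
                r1, c1 = r1 - erosion_px, c1 - erosion_px
                if r1 - r0 < 1 or c1 - c0 < 1:
                    continue
                areas.append(
                    ReferenceArea(
                        polygon=shapely.box(c0 * px, r0 * px, c1 * px, r1 * px),
                        change_class=cls,
                        pixel_size=px,
                    )
                )
        no_change = truth_change.classes == CHANGE_NO
        for side in range(no_change_patch_px, 2, -1):
            placed = False
            for _ in range(2000):
                if no_change.shape[0] <= side or no_change.shape[1] <= side:
                    break
                r0 = int(rng.integers(0, no_change.shape[0] - side))
                c0 = int(rng.integers(0, no_change.shape[1] - side))
                if no_change[r0 : r0 + side, c0 : c0 + side].all():
                    areas.append(
                        ReferenceArea(
                            polygon=shapely.box(
                                c0 * px, r0 * px, (c0 + side) * px, (r0 + side) * px
                            ),
                            change_class=CHANGE_NO,
                            pixel_size=px,
                        )
                    )
                    placed = True
                    break
            if placed:
                break
    return areas


def mmu_filter(
    change_map: ChangeMap,
    min_area_m2: float = 400.0,
    connectivity: int = 2,
) -> ChangeMap:
    """Relabel change components of at most ``min_area_m2`` to "no change".

    Connected components (8-connectivity by default) of classes 2 and 3 whose
    area is less than or equal to the threshold are considered unreliable;
    the filter is idempotent.
    """
    px_area = change_map.pixel_size**2
    max_px = int(np.floor(min_area_m2 / px_area))
    out = np.asarray(change_map.classes).copy()
    for cls in (CHANGE_WOODY, CHANGE_BURNT):
        binary = out == cls
        if not binary.any():
            continue
        comp = measure.label(binary, connectivity=connectivity)
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes <= max_px)
        small = small[small != 0]
        if small.size:
            out[np.isin(comp, small)] = CHANGE_NO
    return ChangeMap(
        classes=out,
        years=change_map.years,
        pixel_size=change_map.pixel_size,
        transform=change_map.transform,
        mmu_applied=True,
        code_table=dict(change_map.code_table),
    )
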