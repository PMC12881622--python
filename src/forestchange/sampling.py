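"""Rule-based stratified reference sampling from a (noisy) land-cover raster.

Implements the three sampling rules used for reference-point preparation —
(1) a 10 m internal buffer away from class edges, (2) a minimum distance of
20 m between points, (3) a density cap of 2 points per km² of class area —
plus automatic spectral verification of the labels and stratified
train/validation splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .grids import AnnualMosaic, BandStack, LabelRaster

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "row", "col", "x", "y", "land_cover", "forest_flag", "leaf_type", "role", "source",
]

_WOODY = {1: "coniferous", 2: "broadleaved"}


@dataclass
class SampleSet:
    """Labelled point samples with their provenance.

    ``frame`` has one row per point with grid coordinates (row, col), world
    coordinates (x, y), the land-cover class code, the derived forest flag and
    leaf type, the train/validation role, and the sample source.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ParameterError(f"sample frame lacks columns {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "SampleSet":
        return SampleSet(self.frame[mask].reset_index(drop=True), dict(self.provenance))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSet":
        return cls(pd.read_csv(path))


def _attributes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    forest = np.where(np.isin(codes, list(_WOODY)), "forest", "non-forest")
    leaf = np.array([_WOODY.get(int(c), "none") for c in codes])
    return forest, leaf


def build_sample_frame(rows, cols, codes, labels: LabelRaster, source: str) -> pd.DataFrame:
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    codes = np.asarray(codes, dtype=int)
    x, y = labels.transform.xy(rows, cols)
    forest, leaf = _attributes(codes)
    return pd.DataFrame(
        {
            "row": rows, "col": cols, "x": x, "y": y,
            "land_cover": codes, "forest_flag": forest, "leaf_type": leaf,
            "role": "unassigned", "source": source,
        }
    )


def erode_class_regions(labels: LabelRaster, buffer_m: float = 10.0) -> LabelRaster:
    """Remove pixels within ``buffer_m`` of a different class or nodata.

    A morphological erosion per class with a square structuring element of
    radius ``buffer_m / pixel_size`` pixels; classes never gain pixels.
    """
    if buffer_m < 0:
        raise ParameterError("buffer must be >= 0")
    r = buffer_m / labels.pixel_size
    if abs(r - round(r)) > 1e-9:
        raise ParameterError("buffer must be a multiple of the pixel size")
    r = int(round(r))
    out = labels.copy()
    if r == 0:
        return out
    eroded = np.zeros_like(labels.labels)
    footprint = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    for code in np.unique(labels.labels):
        if code == 0:
            continue
        keep = ndimage.binary_erosion(labels.labels == code, structure=footprint)
        eroded[keep] = code
    out.labels = eroded
    return out


def draw_stratified_points(
    eroded: LabelRaster,
    density: float = 2.0,
    min_dist_m: float = 20.0,
    rng_seed: int = 0,
    source: str = "reference-raster",
) -> SampleSet:
    """Per-class uniform random points under density and spacing constraints.

    Each class receives at most ``floor(density x class area in km²)`` points;
    candidates closer than ``min_dist_m`` (world distance) to any already
    accepted point — across all classes — are rejected.  A class whose eroded
    region is empty is skipped with a warning.  Deterministic given the seed.
    """
    if density <= 0:
        raise ParameterError("density must be > 0")
    rng = np.random.default_rng(rng_seed)
    px = eroded.pixel_size
    accepted_rows: list[int] = []
    accepted_cols: list[int] = []
    accepted_codes: list[int] = []
    acc_xy = np.empty((0, 2))
    for code in sorted(int(c) for c in np.unique(eroded.labels) if c != 0):
        pix_r, pix_c = np.nonzero(eroded.labels == code)
        if pix_r.size == 0:
            logger.warning("class %d has no pixels after erosion; skipped", code)
            continue
        area_km2 = pix_r.size * px * px / 1e6
        target = int(np.floor(density * area_km2))
        if target == 0:
            logger.warning("class %d area %.3f km² yields 0 points at density %.1f",
                           code, area_km2, density)
            continue
        order = rng.permutation(pix_r.size)
        taken = 0
        attempts = 0
        for i in order:
            if taken >= target or attempts >= 100 * target:
                break
            attempts += 1
            x, y = eroded.transform.xy(pix_r[i], pix_c[i])
            if acc_xy.size:
                d2 = ((acc_xy - [x, y]) ** 2).sum(axis=1)
                if d2.min() < min_dist_m**2:
                    continue
            acc_xy = np.vstack([acc_xy, [x, y]])
            accepted_rows.append(int(pix_r[i]))
            accepted_cols.append(int(pix_c[i]))
            accepted_codes.append(code)
            taken += 1
    frame = build_sample_frame(accepted_rows, accepted_cols, accepted_codes, eroded, source)
    return SampleSet(
        frame,
        provenance={
            "density_per_km2": density,
            "min_dist_m": min_dist_m,
            "rng_seed": rng_seed,
        },
    )


def point_spectra(samples: SampleSet, stack: BandStack | AnnualMosaic) -> np.ndarray:
    """Band values (n_points, n_bands) at the sample pixels."""
    r = samples.frame["row"].to_numpy()
    c = samples.frame["col"].to_numpy()
    return stack.bands[:, r, c].T


def verify_samples_spectral(
    samples: SampleSet,
    stack: BandStack | AnnualMosaic,
    n_sd: float = 3.0,
    max_bad_bands: int = 3,
    min_points: int = 5,
) -> tuple[SampleSet, pd.DataFrame]:
    """Drop points whose spectra are outliers for their labelled class.

    Per class and band, the median and MAD (scaled by 1.4826 to estimate an
    SD) are computed over the candidate points; a point is dropped when it
    falls outside median ± n_sd x scaled-MAD in more than ``max_bad_bands``
    bands.  Classes with fewer than ``min_points`` points pass unverified.
    Returns the verified set and a per-class drop report.
    """
    frame = samples.frame
    if frame.empty:
        return samples.subset(np.zeros(0, dtype=bool)), pd.DataFrame(
            columns=["land_cover", "n_in", "n_dropped"]
        )
    spectra = point_spectra(samples, stack)
    on_valid = stack.valid_mask[frame["row"].to_numpy(), frame["col"].to_numpy()]
    keep = np.ones(len(frame), dtype=bool)
    report = []
    for code, idx in frame.groupby("land_cover").groups.items():
        sel = frame.index.get_indexer(idx)
        sel = sel[on_valid[sel]]
        if sel.size < min_points:
            logger.warning("class %s: %d points < %d, passed unverified",
                           code, sel.size, min_points)
            report.append({"land_cover": code, "n_in": int(sel.size), "n_dropped": 0})
            continue
        cls = spectra[sel]
        med = np.median(cls, axis=0)
        mad = np.median(np.abs(cls - med), axis=0) * 1.4826
        bad_bands = (np.abs(cls - med) > n_sd * mad).sum(axis=1)
        dropped = bad_bands > max_bad_bands
        keep[sel[dropped]] = False
        report.append(
            {"land_cover": code, "n_in": int(sel.size), "n_dropped": int(dropped.sum())}
        )
    return samples.subset(keep), pd.DataFrame(report)


def split_samples(samples: SampleSet, ratio: float, rng_seed: int = 0) -> SampleSet:
    """Assign per-class stratified train/validation roles.

    ``round(ratio x n)`` points per class become training; a single-point
    class goes entirely to training.  Deterministic given the seed.
    """
    if not (0.0 < ratio < 1.0):
        raise ParameterError("ratio must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    frame = samples.frame.copy()
    roles = np.full(len(frame), "validation", dtype=object)
    for code, idx in frame.groupby("land_cover").groups.items():
        sel = frame.index.get_indexer(idx)
        n = sel.size
        if n == 1:
            logger.warning("class %s has a single point; assigned to train", code)
            roles[sel] = "train"
            continue
        n_train = int(np.floor(ratio * n + 0.5))
        chosen = rng.permutation(n)[:n_train]
        roles[sel[chosen]] = "train"
    frame["role"] = roles
    prov = dict(samples.provenance)
    prov.update({"split_ratio": ratio, "split_seed": rng_seed})
    return SampleSet(frame, prov)
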