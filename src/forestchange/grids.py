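"""Raster data model, GeoTIFF I/O, resampling, cloud masking and seasonal compositing.

All rasters live on a plain affine grid: world coordinates are pixel indices
scaled by the pixel size, with y increasing downward (row direction).  Pixel
centres sit at half-integer grid coordinates; the grid is half-open, a pixel
covers [row, row+1) x [col, col+1).  Reflectance is held as float32 in [0, 1];
files written with an integer dtype declare a 1/10000 scale factor, following
the Sentinel-2 surface-reflectance convention.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage

from .errors import EmptyMosaicError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: The ten Sentinel-2 bands used throughout; 60 m bands (B1, B9, B10) excluded.
BAND_NAMES: tuple[str, ...] = (
    "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12",
)

#: SCL-like codes treated as cloud shadow or cloud (3 = shadow, 8/9 = cloud
#: medium/high probability, 10 = thin cirrus).
SHADOW_CLOUD_SCL_CODES: frozenset[int] = frozenset({3, 8, 9, 10})

#: Default cloud-probability cutoff (fraction).
DEFAULT_CLOUD_THRESHOLD: float = 0.65


@dataclass(frozen=True)
class Affine:
    """Six-parameter affine transform mapping (col, row) to world (x, y).

    x = a*col + b*row + c ;  y = d*col + e*row + f
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def scale(cls, pixel_size: float) -> "Affine":
        """Plain scaled grid with origin at (0, 0) and y increasing downward."""
        return cls(pixel_size, 0.0, 0.0, 0.0, pixel_size, 0.0)

    def xy(self, row, col, offset: str = "center"):
        """World coordinates of a pixel; ``offset='center'`` gives its centre."""
        shift = 0.5 if offset == "center" else 0.0
        col = np.asarray(col, dtype=float) + shift
        row = np.asarray(row, dtype=float) + shift
        return self.a * col + self.b * row + self.c, self.d * col + self.e * row + self.f

    def rowcol(self, x, y):
        """Inverse mapping world -> fractional (row, col)."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ParameterError("singular affine transform")
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        col = (self.e * x - self.b * y) / det
        row = (-self.d * x + self.a * y) / det
        return row, col

    def to_list(self) -> list[float]:
        return [self.a, self.b, self.c, self.d, self.e, self.f]


@dataclass
class BandStack:
    """One acquisition: 10 named reflectance bands plus a validity mask.

    Parameters
    ----------
    bands : float32 array of shape (10, rows, cols), values in [0, 1]
    valid_mask : bool array (rows, cols); True marks usable pixels
    pixel_size : nominal ground sampling distance in metres
    transform : affine grid-to-world mapping
    date : acquisition date
    """

    bands: np.ndarray
    valid_mask: np.ndarray
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))
    date: datetime.date | None = None
    band_names: tuple[str, ...] = BAND_NAMES

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float32)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(self.band_names):
            raise FormatError(
                f"expected {len(self.band_names)} bands, got shape {self.bands.shape}"
            )
        if self.valid_mask.shape != self.bands.shape[1:]:
            raise FormatError("valid_mask shape differs from band shape")
        if tuple(self.band_names) != BAND_NAMES:
            raise FormatError(f"band set must be exactly {BAND_NAMES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[self.band_names.index(name)]
        except ValueError as exc:
            raise FormatError(f"band {name!r} not present") from exc

    def copy(self) -> "BandStack":
        return dataclasses.replace(
            self, bands=self.bands.copy(), valid_mask=self.valid_mask.copy()
        )


@dataclass
class AnnualMosaic:
    """Per-pixel, per-band median of the unmasked observations in a season window."""

    bands: np.ndarray
    count: np.ndarray
    year: int
    season_window: tuple[int, int]
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))
    band_names: tuple[str, ...] = BAND_NAMES

    @property
    def valid_mask(self) -> np.ndarray:
        return self.count > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[self.band_names.index(name)]
        except ValueError as exc:
            raise FormatError(f"band {name!r} not present") from exc


@dataclass
class LabelRaster:
    """Categorical land-cover grid; 0 encodes nodata."""

    labels: np.ndarray
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))
    code_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != 0

    def copy(self) -> "LabelRaster":
        return dataclasses.replace(self, labels=self.labels.copy(),
                                   code_table=dict(self.code_table))


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile-backed; metadata carried in the ImageDescription tag)
# ---------------------------------------------------------------------------

def write_raster(stack: BandStack, path) -> None:
    """Write a BandStack as a multi-band float32 GeoTIFF; masked pixels become NaN."""
    data = stack.bands.astype(np.float32).copy()
    data[:, ~stack.valid_mask] = np.nan
    meta = {
        "kind": "bandstack",
        "band_names": list(stack.band_names),
        "pixel_size": stack.pixel_size,
        "transform": stack.transform.to_list(),
        "date": stack.date.isoformat() if stack.date else None,
        "nodata": "nan",
        "scale": 1.0,
    }
    tifffile.imwrite(path, data, photometric="minisblack", description=json.dumps(meta))


def read_raster(path) -> BandStack:
    """Read a multi-band GeoTIFF written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: missing or unreadable raster metadata") from exc
    names = tuple(meta.get("band_names", ()))
    if names != BAND_NAMES:
        missing = set(BAND_NAMES) - set(names)
        raise FormatError(f"{path}: band set {names} != expected; missing {sorted(missing)}")
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3 or data.shape[0] != len(names):
        raise FormatError(f"{path}: expected ({len(names)}, rows, cols), got {data.shape}")
    valid = np.all(np.isfinite(data), axis=0)
    data = np.nan_to_num(data, nan=0.0)
    date = datetime.date.fromisoformat(meta["date"]) if meta.get("date") else None
    return BandStack(
        bands=data,
        valid_mask=valid,
        pixel_size=float(meta.get("pixel_size", 10.0)),
        transform=Affine(*meta.get("transform", Affine.scale(10.0).to_list())),
        date=date,
    )


def write_labels(raster: LabelRaster, path) -> None:
    """Write a categorical raster as int16 GeoTIFF with its code table in metadata."""
    meta = {
        "kind": "labels",
        "pixel_size": raster.pixel_size,
        "transform": raster.transform.to_list(),
        "nodata": 0,
        "code_table": {str(k): v for k, v in raster.code_table.items()},
    }
    tifffile.imwrite(path, raster.labels.astype(np.int16), description=json.dumps(meta))


def read_labels(path) -> LabelRaster:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: missing label metadata") from exc
    return LabelRaster(
        labels=np.asarray(data, dtype=np.int16),
        pixel_size=float(meta.get("pixel_size", 10.0)),
        transform=Affine(*meta.get("transform", Affine.scale(10.0).to_list())),
        code_table={int(k): v for k, v in meta.get("code_table", {}).items()},
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_bilinear(band: np.ndarray, src_pixel: float, dst_pixel: float) -> np.ndarray:
    """Bilinearly resample a single band from a coarse to a finer grid.

    The source pixel size must be an integer multiple of the target (the
    Sentinel-2 case is 20 m -> 10 m).  Target pixel centres are mapped into
    fractional source-pixel coordinates so the two grids stay centre-aligned;
    values beyond the outermost source centres are edge-extended.
    """
    band = np.asarray(band, dtype=np.float64)
    if band.ndim != 2:
        raise ParameterError("resample_bilinear expects a 2-D band")
    ratio = src_pixel / dst_pixel
    if ratio < 1 or abs(ratio - round(ratio)) > 1e-9:
        raise ParameterError(
            f"source pixel ({src_pixel} m) must be an integer multiple of target ({dst_pixel} m)"
        )
    ratio = int(round(ratio))
    out_shape = (band.shape[0] * ratio, band.shape[1] * ratio)
    # target centre j sits at world (j+0.5)*dst; in source pixel units that is
    # (j+0.5)/ratio - 0.5
    rows = (np.arange(out_shape[0]) + 0.5) / ratio - 0.5
    cols = (np.arange(out_shape[1]) + 0.5) / ratio - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(band, [rr, cc], order=1, mode="nearest")


# ---------------------------------------------------------------------------
# Cloud masking
# ---------------------------------------------------------------------------

def apply_cloud_mask(
    stack: BandStack,
    cloud_probability: np.ndarray,
    scl_like: np.ndarray,
    threshold: float = DEFAULT_CLOUD_THRESHOLD,
    shadow_codes: frozenset[int] = SHADOW_CLOUD_SCL_CODES,
) -> BandStack:
    """Invalidate pixels flagged by a cloud-probability grid or SCL-like codes.

    Reflectance values are never altered; only the validity mask shrinks.
    """
    cloud_probability = np.asarray(cloud_probability, dtype=float)
    scl_like = np.asarray(scl_like)
    if cloud_probability.shape != stack.shape or scl_like.shape != stack.shape:
        raise ParameterError("cloud probability / SCL grids must match the stack shape")
    bad = (cloud_probability >= threshold) | np.isin(scl_like, list(shadow_codes))
    out = stack.copy()
    out.valid_mask &= ~bad
    return out


def gap_fill(stack: BandStack, mosaic: "AnnualMosaic") -> BandStack:
    """Fill a stack's cloud-masked pixels with the seasonal median composite.

    Standard practice before stacking multi-date features: a pixel masked in
    one acquisition takes that band's median over the season, so the stacked
    feature vector stays complete wherever the season saw the ground at all.
    """
    if mosaic.shape != stack.shape:
        raise ParameterError("mosaic and stack are not co-registered")
    out = stack.copy()
    hole = ~stack.valid_mask & mosaic.valid_mask
    out.bands[:, hole] = mosaic.bands[:, hole]
    out.valid_mask = stack.valid_mask | mosaic.valid_mask
    return out


# ---------------------------------------------------------------------------
# Seasonal median compositing
# ---------------------------------------------------------------------------

def seasonal_median_mosaic(
    acquisitions: list[BandStack],
    window: tuple[int, int] = (6, 8),
    year: int | None = None,
) -> AnnualMosaic:
    """Per-pixel, per-band median of the unmasked observations inside a month window.

    A pixel is valid iff at least one unmasked observation fell inside the
    window; with an even observation count the median is the mean of the two
    middle values.  Input order is irrelevant by construction.
    """
    selected = []
    for acq in acquisitions:
        if acq.date is None:
            raise ParameterError("acquisition without a date cannot be windowed")
        if year is not None and acq.date.year != year:
            continue
        if window[0] <= acq.date.month <= window[1]:
            selected.append(acq)
    if not selected:
        raise EmptyMosaicError(
            f"no acquisitions in months {window[0]}-{window[1]}"
            + (f" of {year}" if year is not None else "")
        )
    ref = selected[0]
    data = np.stack([a.bands for a in selected])          # (t, 10, r, c)
    valid = np.stack([a.valid_mask for a in selected])    # (t, r, c)
    data = np.where(valid[:, None], data, np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        med = np.nanmedian(data, axis=0)
    count = valid.sum(axis=0).astype(np.int32)
    med = np.nan_to_num(med, nan=0.0).astype(np.float32)
    years = {a.date.year for a in selected}
    return AnnualMosaic(
        bands=med,
        count=count,
        year=year if year is not None else min(years),
        season_window=window,
        pixel_size=ref.pixel_size,
        transform=ref.transform,
        band_names=ref.band_names,
    )
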