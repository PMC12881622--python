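"""Spectral indices, year-to-year differencing, and the 3-sigma candidate mask.

NDVI = (B8 - B4) / (B8 + B4) and NBR = (B8 - B12) / (B8 + B12), the standard
definitions.  Differences are oriented ``year1 - year2`` so that vegetation
loss produces *positive* values, and the exceedance test for candidate change
is one-sided on the loss side: a pixel is a candidate when its difference
exceeds mean + k*SD, with the statistics computed over the valid pixels of
the evaluation domain (normally the year-1 forest mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ParameterError
from .grids import Affine, AnnualMosaic

INDEX_BANDS = {"NDVI": ("B8", "B4"), "NBR": ("B8", "B12")}


@dataclass
class IndexRaster:
    """A single-band index grid in [-1, 1] with NaN nodata."""

    values: np.ndarray
    index_name: str
    year: int
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class DifferenceRaster:
    """Between-year index difference with its domain statistics."""

    values: np.ndarray
    index_name: str
    years: tuple[int, int]
    mean: float
    sd: float
    domain: np.ndarray | None = None
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class CandidateMask:
    """Potential-loss pixels from the k-sigma exceedance rule."""

    mask: np.ndarray
    k: float
    rule: str
    years: tuple[int, int]


def _index(mosaic: AnnualMosaic, name: str) -> IndexRaster:
    plus, minus = INDEX_BANDS[name]
    a = mosaic.band(plus).astype(np.float64)
    b = mosaic.band(minus).astype(np.float64)
    denom = a + b
    values = np.full(mosaic.shape, np.nan)
    ok = mosaic.valid_mask & (denom != 0)
    values[ok] = (a[ok] - b[ok]) / denom[ok]
    return IndexRaster(
        values=values,
        index_name=name,
        year=mosaic.year,
        pixel_size=mosaic.pixel_size,
        transform=mosaic.transform,
    )


def ndvi(mosaic: AnnualMosaic) -> IndexRaster:
    """Normalized Difference Vegetation Index, (B8 - B4) / (B8 + B4)."""
    return _index(mosaic, "NDVI")


def nbr(mosaic: AnnualMosaic) -> IndexRaster:
    """Normalised Burn Ratio, (B8 - B12) / (B8 + B12)."""
    return _index(mosaic, "NBR")


def index_difference(
    index_t1: IndexRaster,
    index_t2: IndexRaster,
    domain: np.ndarray | None = None,
) -> DifferenceRaster:
    """Difference index(t1) - index(t2) for consecutive years, with domain stats.

    ``domain`` is a boolean grid (typically the year-1 forest mask) over which
    the mean and standard deviation are computed; None means all valid pixels.
    """
    if index_t1.index_name != index_t2.index_name:
        raise ParameterError(
            f"index names differ: {index_t1.index_name} vs {index_t2.index_name}"
        )
    if index_t2.year != index_t1.year + 1:
        raise ParameterError(
            f"years must be consecutive, got {index_t1.year} and {index_t2.year}"
        )
    if index_t1.values.shape != index_t2.values.shape:
        raise ParameterError("index rasters are not co-registered")
    values = index_t1.values - index_t2.values
    stat_mask = np.isfinite(values)
    if domain is not None:
        domain = np.asarray(domain, dtype=bool)
        if domain.shape != values.shape:
            raise ParameterError("domain mask is not co-registered")
        stat_mask &= domain
    pool = values[stat_mask]
    mean = float(pool.mean()) if pool.size else float("nan")
    sd = float(pool.std()) if pool.size else float("nan")
    return DifferenceRaster(
        values=values,
        index_name="d" + index_t1.index_name,
        years=(index_t1.year, index_t2.year),
        mean=mean,
        sd=sd,
        domain=domain,
        pixel_size=index_t1.pixel_size,
        transform=index_t1.transform,
    )


def candidate_change_mask(
    dndvi: DifferenceRaster,
    dnbr: DifferenceRaster,
    k: float = 3.0,
    rule: str = "union",
) -> CandidateMask:
    """Flag pixels whose loss-direction difference exceeds mean + k*SD.

    ``rule='union'`` flags a pixel when either difference exceeds its own
    threshold (maximises candidate recall); ``'intersection'`` requires both.
    A zero-SD domain yields an empty mask.
    """
    if k <= 0:
        raise ParameterError("k must be > 0")
    if rule not in ("union", "intersection"):
        raise ParameterError(f"unknown combination rule {rule!r}")
    if dndvi.values.shape != dnbr.values.shape:
        raise ParameterError("difference rasters are not co-registered")
    if dndvi.years != dnbr.years:
        raise ParameterError("difference rasters cover different year pairs")

    def exceed(diff: DifferenceRaster) -> np.ndarray:
        out = np.zeros(diff.values.shape, dtype=bool)
        ok = np.isfinite(diff.values)
        if diff.domain is not None:
            ok &= diff.domain
        if np.isfinite(diff.sd):
            out[ok] = diff.values[ok] > diff.mean + k * diff.sd
        return out

    a, b = exceed(dndvi), exceed(dnbr)
    mask = (a | b) if rule == "union" else (a & b)
    return CandidateMask(mask=mask, k=float(k), rule=rule, years=dndvi.years)
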