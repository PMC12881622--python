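"""Synthetic multi-year scene generator with known truth.

Generates Sentinel-2-like 10-band acquisitions over a landscape of spectrally
distinct land-cover classes, injects known change events (clearings and
burns), stamps rectangular cloud masks, and produces a deliberately noisy
mock reference land-cover product emulating the ~75% accuracy of global
land-cover maps.  Every downstream stage of the pipeline can therefore be
tested against exact truth without any satellite download.

Land-cover codes (the code table written with every label raster)::

    1 coniferous   2 broadleaved   3 sealed     4 grassland   5 cropland
    6 bare_soil    7 wetland       8 water      9 burnt      10 cleared

Codes 9 and 10 are post-disturbance surfaces: they appear only in truth
labels of years at or after a change event.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .changes import CHANGE_BURNT, CHANGE_NO, CHANGE_OUTSIDE, CHANGE_WOODY, ChangeMap
from .errors import ConfigurationError, ParameterError
from .geometry import polygon_pixel_mask
from .grids import BAND_NAMES, Affine, BandStack, LabelRaster

CLASS_CODES: dict[str, int] = {
    "coniferous": 1,
    "broadleaved": 2,
    "sealed": 3,
    "grassland": 4,
    "cropland": 5,
    "bare_soil": 6,
    "wetland": 7,
    "water": 8,
    "burnt": 9,
    "cleared": 10,
}
CODE_NAMES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}

#: Codes counted as woody (tree) cover.
WOODY_CODES: frozenset[int] = frozenset({1, 2})
#: The eight stable land-cover classes a reference product would map.
BASE_CODES: tuple[int, ...] = tuple(range(1, 9))


@dataclass(frozen=True)
class SpectralSignature:
    """Per-class spectral behaviour: band means, seasonal swing, pixel noise.

    ``band_means`` are surface reflectances in [0, 1] for the 10 bands in
    :data:`forestchange.grids.BAND_NAMES` order.  The seasonal term is a
    per-band sinusoid over day-of-year with the given amplitude; pixel noise
    is i.i.d. Gaussian per band with the given standard deviation.
    """

    class_id: int
    band_means: tuple[float, ...]
    seasonal_amplitude: tuple[float, ...] = (0.0,) * 10
    noise_sd: tuple[float, ...] = (0.0,) * 10

    def validate(self) -> None:
        if len(self.band_means) != len(BAND_NAMES):
            raise ConfigurationError("band_means must have 10 entries")
        for m, a, s in zip(self.band_means, self.seasonal_amplitude, self.noise_sd):
            if not (0.0 <= m - a and m + a <= 1.0):
                raise ConfigurationError(
                    f"class {self.class_id}: mean {m} ± amplitude {a} leaves [0, 1]"
                )
            if s < 0:
                raise ConfigurationError("noise_sd must be >= 0")


def _sig(code, means, amp=0.005, sd=0.01):
    return SpectralSignature(
        class_id=code,
        band_means=tuple(means),
        seasonal_amplitude=(amp,) * 10,
        noise_sd=(sd,) * 10,
    )


#: Default signature library.  Values are plausible growing-season surface
#: reflectances chosen so that class means sit well clear of one another at
#: the default per-band noise SD of 0.01, and so that the disturbance classes
#: have the right index behaviour: the burnt surface has lower NIR (B8) and
#: higher SWIR2 (B12) than any woody class (NBR drops after a burn), and the
#: cleared surface has lower NDVI than the woody classes.
DEFAULT_SIGNATURES: dict[int, SpectralSignature] = {
    s.class_id: s
    for s in [
        #            B2     B3     B4     B5     B6     B7     B8     B8A    B11    B12
        _sig(1, (0.020, 0.040, 0.030, 0.060, 0.150, 0.180, 0.300, 0.320, 0.120, 0.060)),
        _sig(2, (0.030, 0.060, 0.040, 0.090, 0.250, 0.300, 0.450, 0.470, 0.180, 0.080)),
        _sig(3, (0.120, 0.140, 0.160, 0.180, 0.190, 0.200, 0.220, 0.220, 0.250, 0.240)),
        _sig(4, (0.040, 0.080, 0.070, 0.120, 0.220, 0.260, 0.350, 0.370, 0.240, 0.140)),
        _sig(5, (0.050, 0.090, 0.100, 0.140, 0.200, 0.230, 0.300, 0.310, 0.280, 0.180)),
        _sig(6, (0.100, 0.140, 0.180, 0.220, 0.250, 0.270, 0.300, 0.310, 0.380, 0.320)),
        _sig(7, (0.030, 0.060, 0.050, 0.080, 0.140, 0.160, 0.220, 0.230, 0.130, 0.070)),
        _sig(8, (0.030, 0.040, 0.030, 0.030, 0.020, 0.020, 0.010, 0.010, 0.010, 0.010)),
        _sig(9, (0.040, 0.050, 0.060, 0.070, 0.080, 0.090, 0.120, 0.120, 0.280, 0.300)),
        _sig(10, (0.070, 0.100, 0.120, 0.150, 0.180, 0.200, 0.240, 0.250, 0.300, 0.240)),
    ]
}


@dataclass(frozen=True)
class ChangeEvent:
    """A disturbance polygon applied from ``year`` onward.

    ``kind`` is ``"clearing"`` (woody -> cleared surface, code 10) or
    ``"burn"`` (woody -> burnt surface, code 9).  The polygon is given in
    world coordinates of the scene grid.
    """

    polygon: shapely.Geometry
    year: int
    kind: str

    def __post_init__(self):
        if self.kind not in ("clearing", "burn"):
            raise ConfigurationError(f"unknown change kind {self.kind!r}")

    @property
    def post_code(self) -> int:
        return CLASS_CODES["cleared"] if self.kind == "clearing" else CLASS_CODES["burnt"]

    @property
    def change_code(self) -> int:
        return CHANGE_WOODY if self.kind == "clearing" else CHANGE_BURNT


#: Default acquisition dates (month, day): one spring date plus three inside
#: the June-August mosaic window, mirroring the 3-5 usable images per scene
#: a practitioner would keep from one vegetation season.
DEFAULT_ACQUISITION_DATES: tuple[tuple[int, int], ...] = (
    (4, 20), (6, 10), (7, 15), (8, 20),
)

#: Default class layout: Voronoi seed counts per class code; woody classes get
#: enough seeds to cover roughly half the landscape, as in a densely forested
#: study region.
DEFAULT_BLOB_SEEDS: dict[int, int] = {1: 6, 2: 6, 3: 1, 4: 3, 5: 4, 6: 1, 7: 1, 8: 1}


@dataclass
class SceneConfig:
    """Everything needed to generate one synthetic region deterministically."""

    rows: int = 128
    cols: int = 128
    pixel_size: float = 10.0
    years: tuple[int, ...] = (2020, 2021)
    acquisition_dates: tuple[tuple[int, int], ...] = DEFAULT_ACQUISITION_DATES
    rng_seed: int = 0
    blob_seeds: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_BLOB_SEEDS))
    label_noise_rate: float = 0.25
    label_noise_cluster_px: int = 4
    cloud_fraction: float = 0.05
    change_events: list[ChangeEvent] = field(default_factory=list)

    @property
    def transform(self) -> Affine:
        return Affine.scale(self.pixel_size)

    def validate(self, signatures: dict[int, SpectralSignature]) -> None:
        if len(self.years) < 2:
            raise ConfigurationError("at least two years are required")
        if tuple(sorted(self.years)) != tuple(self.years):
            raise ConfigurationError("years must be sorted ascending")
        if not (0.0 <= self.label_noise_rate < 1.0):
            raise ParameterError("label_noise_rate must be in [0, 1)")
        if not (0.0 <= self.cloud_fraction < 1.0):
            raise ParameterError("cloud_fraction must be in [0, 1)")
        for code in self.blob_seeds:
            if code not in signatures:
                raise ConfigurationError(f"class {code} in layout has no signature")
        for needed in (CLASS_CODES["burnt"], CLASS_CODES["cleared"]):
            if any(e.post_code == needed for e in self.change_events) and needed not in signatures:
                raise ConfigurationError(f"change events need signature for class {needed}")
        width = self.cols * self.pixel_size
        height = self.rows * self.pixel_size
        frame = shapely.box(0, 0, width, height)
        for ev in self.change_events:
            if ev.year not in self.years[1:]:
                raise ConfigurationError(
                    f"change event year {ev.year} must be a configured year after the first"
                )
            if not frame.covers(ev.polygon):
                raise ConfigurationError("change polygon lies outside the grid")


@dataclass
class SceneTruth:
    """Exact truth for one generated scene."""

    truth_labels: dict[int, LabelRaster]
    truth_change: dict[tuple[int, int], ChangeMap]
    mock_reference: LabelRaster


def generate_layout(config: SceneConfig, rng: np.random.Generator) -> LabelRaster:
    """Voronoi-tessellated class layout: contiguous blobs, one class per cell."""
    codes = [c for c, n in config.blob_seeds.items() for _ in range(n)]
    pts = rng.uniform(0, 1, size=(len(codes), 2)) * [config.rows, config.cols]
    tree = cKDTree(pts)
    rr, cc = np.meshgrid(
        np.arange(config.rows) + 0.5, np.arange(config.cols) + 0.5, indexing="ij"
    )
    _, idx = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    labels = np.asarray(codes, dtype=np.int16)[idx].reshape(config.rows, config.cols)
    return LabelRaster(
        labels=labels,
        pixel_size=config.pixel_size,
        transform=config.transform,
        code_table=dict(CODE_NAMES),
    )


def apply_label_noise(
    labels: LabelRaster, rate: float, rng_seed: int, cluster_px: int = 1
) -> LabelRaster:
    """Relabel exactly ``round(rate * valid pixels)`` pixels to a different class.

    Emulates the label error of a global land-cover product used as reference
    data.  With ``cluster_px`` > 1 the wrong labels arrive in square patches
    of roughly that side (misclassified fields and stands are spatially
    coherent in real products, not salt-and-pepper); the relabelled pixel
    count is exact in either mode.  Replacement labels always differ from the
    pixel's own class; deterministic given the seed.
    """
    if not (0.0 <= rate < 1.0):
        raise ParameterError("rate must be in [0, 1)")
    out = labels.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(rng_seed)
    flat = out.labels.ravel()
    valid_idx = np.flatnonzero(labels.labels.ravel() != 0)
    n_noise = int(round(rate * valid_idx.size))
    if n_noise == 0:
        return out
    if cluster_px <= 1:
        chosen = rng.choice(valid_idx, size=n_noise, replace=False)
    else:
        rows, cols = labels.shape
        noised = np.zeros(flat.size, dtype=bool)
        picked: list[np.ndarray] = []
        total = 0
        guard = 0
        while total < n_noise and guard < 100000:
            guard += 1
            side = int(rng.integers(max(1, cluster_px // 2), cluster_px + 1))
            r0 = int(rng.integers(0, max(1, rows - side + 1)))
            c0 = int(rng.integers(0, max(1, cols - side + 1)))
            rr, cc = np.meshgrid(
                np.arange(r0, min(rows, r0 + side)),
                np.arange(c0, min(cols, c0 + side)),
                indexing="ij",
            )
            idx = (rr * cols + cc).ravel()
            idx = idx[(flat[idx] != 0) & ~noised[idx]]
            if idx.size == 0:
                continue
            idx = idx[: n_noise - total]
            noised[idx] = True
            picked.append(idx)
            total += idx.size
        # one offset per patch keeps the wrong labels spatially coherent,
        # like a misclassified field or stand in a real product
        for idx in picked:
            offset = int(rng.integers(1, len(BASE_CODES)))
            flat[idx] = ((flat[idx] - 1 + offset) % len(BASE_CODES) + 1).astype(np.int16)
        return out
    current = flat[chosen]
    # a uniform offset 1..7 wrapped within the 8 base classes is always a
    # different, valid class
    offsets = rng.integers(1, len(BASE_CODES), size=chosen.size)
    flat[chosen] = ((current - 1 + offsets) % len(BASE_CODES) + 1).astype(np.int16)
    return out


def _cloud_mask(shape, fraction, rng) -> np.ndarray:
    """Random rectangles until at least ``fraction`` of the grid is cloudy."""
    cloudy = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return cloudy
    target = fraction * cloudy.size
    guard = 0
    while cloudy.sum() < target and guard < 1000:
        h = int(rng.integers(max(2, shape[0] // 10), max(3, shape[0] // 3)))
        w = int(rng.integers(max(2, shape[1] // 10), max(3, shape[1] // 3)))
        r0 = int(rng.integers(0, shape[0] - h + 1))
        c0 = int(rng.integers(0, shape[1] - w + 1))
        cloudy[r0 : r0 + h, c0 : c0 + w] = True
        guard += 1
    return cloudy


def _seasonal_factor(date: datetime.date) -> float:
    doy = date.timetuple().tm_yday
    return math.sin(2.0 * math.pi * (doy - 80) / 365.0)


def make_scene(
    config: SceneConfig,
    signatures: dict[int, SpectralSignature] | None = None,
) -> tuple[dict[int, list[BandStack]], SceneTruth]:
    """Generate all acquisitions and the exact truth for one scene.

    Returns a mapping year -> list of cloud-masked acquisitions, plus the
    per-year truth labels, per-year-pair truth change maps, and the noisy mock
    reference product (year-1 truth with label noise).
    """
    signatures = dict(DEFAULT_SIGNATURES if signatures is None else signatures)
    for sig in signatures.values():
        sig.validate()
    config.validate(signatures)
    # the layout is reproducible from the seed alone, so callers can place
    # change events against generate_layout(config, default_rng(seed))
    layout = generate_layout(config, np.random.default_rng(config.rng_seed))
    noise_seed, pixel_ss = np.random.SeedSequence(config.rng_seed).spawn(2)

    # per-year truth labels: events apply from their year onward
    truth_labels: dict[int, LabelRaster] = {}
    event_masks: list[tuple[ChangeEvent, np.ndarray]] = []
    for ev in config.change_events:
        mask = polygon_pixel_mask(ev.polygon, layout.shape, config.transform)
        if not mask.any():
            raise ConfigurationError("change polygon covers no pixel centre")
        event_masks.append((ev, mask))
    for year in config.years:
        labels = layout.labels.copy()
        for ev, mask in sorted(event_masks, key=lambda em: em[0].year):
            if ev.year <= year:
                prior = labels[mask]
                if ev.year == year and not np.isin(prior, list(WOODY_CODES)).all():
                    raise ConfigurationError(
                        f"{ev.kind} polygon in {ev.year} covers non-woody truth pixels"
                    )
                labels[mask] = ev.post_code
        truth_labels[year] = dataclasses.replace(layout, labels=labels)

    # truth change maps for consecutive year pairs
    truth_change: dict[tuple[int, int], ChangeMap] = {}
    for y1, y2 in zip(config.years[:-1], config.years[1:]):
        woody = np.isin(truth_labels[y1].labels, list(WOODY_CODES))
        change = np.where(woody, CHANGE_NO, CHANGE_OUTSIDE).astype(np.int16)
        for ev, mask in event_masks:
            if ev.year == y2:
                change[mask & woody] = ev.change_code
        truth_change[(y1, y2)] = ChangeMap(
            classes=change,
            years=(y1, y2),
            pixel_size=config.pixel_size,
            transform=config.transform,
        )

    mock_reference = apply_label_noise(
        truth_labels[config.years[0]],
        config.label_noise_rate,
        int(noise_seed.generate_state(1)[0] % (2**31)),
        cluster_px=config.label_noise_cluster_px,
    )

    # per-class lookup tables for vectorised reflectance synthesis
    max_code = max(signatures)
    means = np.zeros((max_code + 1, len(BAND_NAMES)), dtype=np.float64)
    amps = np.zeros_like(means)
    sds = np.zeros_like(means)
    for code, sig in signatures.items():
        means[code] = sig.band_means
        amps[code] = sig.seasonal_amplitude
        sds[code] = sig.noise_sd

    pixel_rng = np.random.default_rng(pixel_ss)
    acquisitions: dict[int, list[BandStack]] = {}
    for year in config.years:
        labels = truth_labels[year].labels
        acquisitions[year] = []
        for month, day in config.acquisition_dates:
            date = datetime.date(year, month, day)
            season = _seasonal_factor(date)
            refl = means[labels] + season * amps[labels]          # (r, c, 10)
            sd = sds[labels]
            if sd.any():
                refl = refl + pixel_rng.normal(0.0, 1.0, size=refl.shape) * sd
            refl = np.clip(refl, 0.0, 1.0).transpose(2, 0, 1)
            cloudy = _cloud_mask(labels.shape, config.cloud_fraction, pixel_rng)
            acquisitions[year].append(
                BandStack(
                    bands=refl.astype(np.float32),
                    valid_mask=~cloudy,
                    pixel_size=config.pixel_size,
                    transform=config.transform,
                    date=date,
                )
            )
    truth = SceneTruth(
        truth_labels=truth_labels,
        truth_change=truth_change,
        mock_reference=mock_reference,
    )
    return acquisitions, truth


def propose_change_polygons(
    truth: LabelRaster,
    year: int,
    n_clearings: int = 1,
    n_burns: int = 1,
    patch_px: tuple[int, int] = (6, 12),
    rng_seed: int = 0,
) -> list[ChangeEvent]:
    """Find rectangular all-woody patches to use as change events.

    Searches for axis-aligned rectangles fully inside woody cover in the given
    truth labels; returns clearing events first, then burns.  Raises if the
    landscape cannot host the requested events.
    """
    rng = np.random.default_rng(rng_seed)
    woody = np.isin(truth.labels, list(WOODY_CODES))
    px = truth.pixel_size
    events: list[ChangeEvent] = []
    taken = np.zeros_like(woody)
    kinds = ["clearing"] * n_clearings + ["burn"] * n_burns
    for kind in kinds:
        placed = False
        for _ in range(5000):
            h = int(rng.integers(patch_px[0], patch_px[1] + 1))
            w = int(rng.integers(patch_px[0], patch_px[1] + 1))
            if truth.shape[0] <= h or truth.shape[1] <= w:
                continue
            r0 = int(rng.integers(0, truth.shape[0] - h))
            c0 = int(rng.integers(0, truth.shape[1] - w))
            window = np.s_[r0 : r0 + h, c0 : c0 + w]
            if woody[window].all() and not taken[window].any():
                taken[window] = True
                poly = shapely.box(c0 * px, r0 * px, (c0 + w) * px, (r0 + h) * px)
                events.append(ChangeEvent(polygon=poly, year=year, kind=kind))
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"could not place a {kind} patch of {patch_px} px inside woody cover"
            )
    return events
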