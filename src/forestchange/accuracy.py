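"""Error matrices, thematic accuracy metrics, and verification polygons.

Overall accuracy (OA), per-class user's and producer's accuracy (UA, PA),
their harmonic mean (F1), and the chance-corrected Kappa coefficient are all
derived from a K x K error matrix of (map class, reference class) counts.
Verification polygons are 10 x 10 m squares centred on map pixels, drawn
stratified per class after shrinking each class extent inward to avoid edge
pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .errors import ParameterError
from .grids import Affine

logger = logging.getLogger(__name__)


@dataclass
class ErrorMatrix:
    """K x K counts; rows are map classes, columns reference classes."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ParameterError("error-matrix counts must be >= 0")
        if list(self.counts.index) != list(self.counts.columns):
            raise ParameterError("row and column class labels must match")

    @classmethod
    def from_counts(cls, counts, labels) -> "ErrorMatrix":
        arr = np.asarray(counts, dtype=np.int64)
        return cls(pd.DataFrame(arr, index=list(labels), columns=list(labels)))

    @property
    def n(self) -> int:
        return int(self.counts.values.sum())

    @property
    def labels(self) -> list:
        return list(self.counts.index)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def error_matrix(map_grid: np.ndarray, reference: pd.DataFrame,
                 labels=None) -> ErrorMatrix:
    """Cross-tabulate map values against labelled reference items.

    ``reference`` needs columns ``row``, ``col`` and ``label``; polygon-based
    verification contributes its centre pixel, which for 10 x 10 m polygons at
    10 m resolution is exactly the one pixel the polygon covers.  Items off
    the grid are skipped and logged.
    """
    required = {"row", "col", "label"}
    if not required <= set(reference.columns):
        raise ParameterError(f"reference frame needs columns {sorted(required)}")
    r = reference["row"].to_numpy(dtype=int)
    c = reference["col"].to_numpy(dtype=int)
    ok = (r >= 0) & (r < map_grid.shape[0]) & (c >= 0) & (c < map_grid.shape[1])
    if (~ok).any():
        logger.warning("error_matrix: skipped %d off-grid reference items", (~ok).sum())
    mapped = np.asarray(map_grid)[r[ok], c[ok]]
    ref = reference["label"].to_numpy()[ok]
    if labels is None:
        labels = sorted(set(np.unique(mapped)) | set(np.unique(ref)))
    table = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=np.int64)
    for m, g in zip(mapped, ref):
        table.loc[m, g] += 1
    return ErrorMatrix(table)


def metrics(matrix: ErrorMatrix) -> dict:
    """OA, Kappa and per-class UA / PA / F1 from the matrix counts.

    OA = trace / n; UA_i = diagonal_i / row-sum_i; PA_i = diagonal_i /
    column-sum_i; F1_i is the harmonic mean of UA_i and PA_i; Kappa =
    (p_o - p_e) / (1 - p_e) with p_e the chance agreement from the margins.
    Classes with a zero row or column report NaN (undefined), never 0.
    """
    counts = matrix.counts.values.astype(float)
    n = counts.sum()
    if n <= 0:
        raise ParameterError("error matrix is empty")
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(rows > 0, diag / rows, np.nan)
        pa = np.where(cols > 0, diag / cols, np.nan)
        f1 = np.where(ua + pa > 0, 2 * ua * pa / (ua + pa), np.nan)
    p_o = diag.sum() / n
    p_e = float((rows * cols).sum()) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else float("nan")
    labels = matrix.labels
    return {
        "OA": float(p_o),
        "Kappa": float(kappa),
        "UA": dict(zip(labels, ua.tolist())),
        "PA": dict(zip(labels, pa.tolist())),
        "F1": dict(zip(labels, f1.tolist())),
        "n": int(n),
    }


def two_class_matrix_from_user_accuracy(
    per_class_n: int, ua: dict
) -> ErrorMatrix:
    """Reconstruct a 2-class matrix from per-mapped-class UA at fixed row totals.

    Each mapped class contributes ``per_class_n`` verification items; the
    off-diagonal cell of a row receives the items its UA marks as wrong.
    """
    if len(ua) != 2:
        raise ParameterError("exactly two classes required")
    labels = list(ua)
    counts = np.zeros((2, 2), dtype=np.int64)
    for i, lab in enumerate(labels):
        correct = int(round(ua[lab] * per_class_n))
        counts[i, i] = correct
        counts[i, 1 - i] = per_class_n - correct
    return ErrorMatrix.from_counts(counts, labels)


@dataclass
class VerificationPolygonSet:
    """Stratified 10 x 10 m verification squares centred on map pixels."""

    frame: pd.DataFrame            # row, col, map_class
    polygons: list[shapely.Geometry]
    shrink_m: float
    per_class_target: int

    def __len__(self) -> int:
        return len(self.frame)


def generate_verification_polygons(
    map_grid: np.ndarray,
    pixel_size: float = 10.0,
    transform: Affine | None = None,
    per_class_n: int = 100,
    shrink_m: float = 10.0,
    rng_seed: int = 0,
    classes=None,
) -> VerificationPolygonSet:
    """Draw per-class random pixel-centred squares away from class edges.

    Each class extent is shrunk ``shrink_m`` inward (morphological erosion)
    before drawing, so no centre sits within the shrink distance of the class
    boundary; classes too small after shrinking yield fewer polygons, logged.
    Deterministic given the seed.
    """
    if transform is None:
        transform = Affine.scale(pixel_size)
    r = shrink_m / pixel_size
    if abs(r - round(r)) > 1e-9:
        raise ParameterError("shrink distance must be a multiple of the pixel size")
    r = int(round(r))
    rng = np.random.default_rng(rng_seed)
    grid = np.asarray(map_grid)
    if classes is None:
        classes = [c for c in np.unique(grid)]
    rows_out, cols_out, cls_out = [], [], []
    for cls in classes:
        binary = grid == cls
        if r > 0:
            binary = ndimage.binary_erosion(
                binary, structure=np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
            )
        rr, cc = np.nonzero(binary)
        if rr.size == 0:
            logger.warning("class %s empty after %.0f m shrink; no polygons", cls, shrink_m)
            continue
        n = min(per_class_n, rr.size)
        if n < per_class_n:
            logger.warning("class %s: only %d centres available of %d requested",
                           cls, rr.size, per_class_n)
        pick = rng.choice(rr.size, size=n, replace=False)
        rows_out.extend(rr[pick].tolist())
        cols_out.extend(cc[pick].tolist())
        cls_out.extend([cls] * n)
    polys = []
    for row, col in zip(rows_out, cols_out):
        x0, y0 = transform.xy(row, col, offset="corner")
        polys.append(shapely.box(x0, y0, x0 + pixel_size, y0 + pixel_size))
    frame = pd.DataFrame({"row": rows_out, "col": cols_out, "map_class": cls_out})
    return VerificationPolygonSet(
        frame=frame, polygons=polys, shrink_m=shrink_m, per_class_target=per_class_n
    )


def verify_against_truth(
    polygons: VerificationPolygonSet, truth_grid: np.ndarray
) -> pd.DataFrame:
    """Label each verification polygon with the truth value at its centre pixel."""
    frame = polygons.frame.copy()
    frame["label"] = np.asarray(truth_grid)[
        frame["row"].to_numpy(), frame["col"].to_numpy()
    ]
    return frame
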