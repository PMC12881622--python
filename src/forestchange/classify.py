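"""Two-stage random-forest classification: forest mask, then dominant leaf type.

Stage one separates forest from non-forest on the stacked multi-date band
values; stage two labels the dominant leaf type (coniferous vs broadleaved)
only inside the forest mask from stage one.  Models are trained per scene and
can be transferred unchanged to other scenes whose stacks share the same
feature schema (the regime used where forest is too sparse to train locally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError, SchemaError, TrainingError
from .grids import Affine, AnnualMosaic, BandStack
from .sampling import SampleSet

logger = logging.getLogger(__name__)

TASKS = ("forest", "leaf_type", "change")

#: Leaf-type map codes; 1/2 match the land-cover codes for the tree classes.
LEAF_NON_FOREST, LEAF_CONIFEROUS, LEAF_BROADLEAVED = 0, 1, 2


@dataclass
class FeatureTable:
    """Per-sample feature matrix with its label column and fixed schema."""

    X: pd.DataFrame
    y: pd.Series
    task: str
    schema: tuple[str, ...]

    def __post_init__(self) -> None:
        if tuple(self.X.columns) != self.schema:
            raise SchemaError("feature columns do not match the declared schema")
        if self.task not in TASKS:
            raise ParameterError(f"unknown task {self.task!r}")

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class ClassifierModel:
    """A fitted random forest plus the schema it demands.

    Predicts only labels seen in training and refuses feature tables whose
    schema differs from its own.
    """

    estimator: RandomForestClassifier
    task: str
    schema: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def _check(self, schema: tuple[str, ...]) -> None:
        if tuple(schema) != self.schema:
            raise SchemaError(
                f"feature schema mismatch: model expects {len(self.schema)} columns "
                f"{self.schema[:3]}..., got {len(schema)}"
            )

    def predict(self, X: np.ndarray, schema: tuple[str, ...]) -> np.ndarray:
        self._check(schema)
        return self.estimator.predict(np.asarray(X))

    def predict_table(self, table: FeatureTable) -> np.ndarray:
        return self.predict(table.X.to_numpy(), tuple(table.X.columns))

    def save(self, path) -> None:
        joblib.dump(
            {"format_version": 1, "estimator": self.estimator, "task": self.task,
             "schema": list(self.schema), "metadata": self.metadata},
            path,
        )

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        blob = joblib.load(path)
        return cls(
            estimator=blob["estimator"], task=blob["task"],
            schema=tuple(blob["schema"]), metadata=blob.get("metadata", {}),
        )


@dataclass
class ForestMask:
    """Binary forest / non-forest grid."""

    mask: np.ndarray
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))


@dataclass
class LeafTypeMap:
    """Dominant leaf type: 0 non-forest, 1 coniferous, 2 broadleaved."""

    classes: np.ndarray
    pixel_size: float = 10.0
    transform: Affine = field(default_factory=lambda: Affine.scale(10.0))


def _stack_schema(stacks: list[BandStack | AnnualMosaic]) -> tuple[str, ...]:
    cols = []
    for i, stack in enumerate(stacks):
        tag = stack.date.isoformat() if getattr(stack, "date", None) else f"t{i}"
        cols.extend(f"{tag}_{b}" for b in stack.band_names)
    return tuple(cols)


def _task_labels(samples: SampleSet, task: str) -> pd.Series:
    frame = samples.frame
    if task == "forest":
        return (frame["forest_flag"] == "forest").astype(int)
    if task == "leaf_type":
        if (frame["leaf_type"] == "none").any():
            raise ParameterError("leaf_type task requires forest-only samples")
        return frame["leaf_type"].map(
            {"coniferous": LEAF_CONIFEROUS, "broadleaved": LEAF_BROADLEAVED}
        )
    raise ParameterError(f"task {task!r} has no label rule here")


def extract_features(
    stacks: list[BandStack | AnnualMosaic],
    samples: SampleSet,
    task: str = "forest",
) -> FeatureTable:
    """One row per sample; 10 band columns per acquisition date.

    Rows touching an invalid (cloud-masked) pixel in *any* stack are dropped
    and logged.
    """
    if not stacks:
        raise ParameterError("at least one stack is required")
    schema = _stack_schema(stacks)
    frame = samples.frame
    r = frame["row"].to_numpy()
    c = frame["col"].to_numpy()
    blocks = []
    valid = np.ones(len(frame), dtype=bool)
    for stack in stacks:
        blocks.append(stack.bands[:, r, c].T)
        valid &= stack.valid_mask[r, c]
    X = pd.DataFrame(np.hstack(blocks), columns=list(schema))
    y = _task_labels(samples, task)
    dropped = int((~valid).sum())
    if dropped:
        logger.info("extract_features: dropped %d rows on invalid pixels", dropped)
    X = X[valid].reset_index(drop=True)
    y = y[valid].reset_index(drop=True)
    if X.empty:
        raise ParameterError("no valid rows: every sample hit an invalid pixel")
    return FeatureTable(X=X, y=y, task=task, schema=schema)


def scene_feature_matrix(
    stacks: list[BandStack | AnnualMosaic],
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Feature matrix for every pixel of a scene.

    Returns (X of shape (rows*cols, n_features), valid mask grid, schema);
    a pixel is valid only if unmasked in every stack.
    """
    schema = _stack_schema(stacks)
    shape = stacks[0].shape
    valid = np.ones(shape, dtype=bool)
    blocks = []
    for stack in stacks:
        if stack.shape != shape:
            raise ParameterError("stacks are not co-registered")
        blocks.append(stack.bands.reshape(len(stack.band_names), -1).T)
        valid &= stack.valid_mask
    return np.hstack(blocks), valid, schema


def train_model(
    table: FeatureTable,
    task: str | None = None,
    n_trees: int = 100,
    rng_seed: int = 0,
) -> ClassifierModel:
    """Fit a random forest (100 trees by default, sqrt-features per split).

    Training accuracy is estimated out-of-bag and stored in the model
    metadata; fitting is deterministic given the seed.
    """
    task = task or table.task
    classes = np.unique(table.y)
    if classes.size < 2:
        raise TrainingError(f"training table has a single class {classes.tolist()}")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=int(rng_seed),
        n_jobs=1,
    )
    with np.errstate(all="ignore"):
        rf.fit(table.X.to_numpy(), table.y.to_numpy())
    oob = float(rf.oob_score_) if hasattr(rf, "oob_score_") else float("nan")
    logger.info("trained %s model: %d samples, OOB accuracy %.3f", task, len(table), oob)
    return ClassifierModel(
        estimator=rf,
        task=task,
        schema=table.schema,
        metadata={
            "n_trees": n_trees, "rng_seed": int(rng_seed),
            "n_samples": len(table), "oob_accuracy": oob,
            "classes": classes.tolist(),
        },
    )


def classify_scene(
    stacks: list[BandStack | AnnualMosaic],
    model: ClassifierModel,
    within_mask: ForestMask | None = None,
) -> ForestMask | LeafTypeMap:
    """Label every valid pixel of a scene with a fitted model.

    With ``within_mask`` given (the leaf-type stage), pixels outside the mask
    are labelled non-forest and never shown to the model.
    """
    X, valid, schema = scene_feature_matrix(stacks)
    shape = stacks[0].shape
    domain = valid.copy()
    if within_mask is not None:
        domain &= within_mask.mask
    flat = domain.ravel()
    pred = np.zeros(flat.size, dtype=np.int16)
    if flat.any():
        pred[flat] = model.predict(X[flat], schema)
    grid = pred.reshape(shape)
    ref = stacks[0]
    if model.task == "forest":
        return ForestMask(mask=grid.astype(bool) & valid,
                          pixel_size=ref.pixel_size, transform=ref.transform)
    if model.task == "leaf_type":
        return LeafTypeMap(classes=grid, pixel_size=ref.pixel_size, transform=ref.transform)
    raise ParameterError(f"classify_scene cannot handle task {model.task!r}")
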