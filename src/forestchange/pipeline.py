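"""End-to-end orchestration: scenes -> classification -> change -> accuracy -> report.

A single :class:`PipelineConfig` drives every stage with the method's
standard settings as defaults: an April-September window for classification
stacks, June-August median mosaics for change detection, a 60/40
train/validation split for the cover and leaf-type models, 7:3 for the
change model, 10 m edge buffer, 20 m point spacing, a 3-sigma candidate
threshold, a 400 m² minimum mapping unit, and 100-tree random forests.  The
change model is trained on the first region and first year pair and
transferred unchanged to the remaining regions and periods.

Every run writes its outputs with provenance metadata (config hash and
seeds); reruns with the same config are byte-identical on the categorical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import accuracy as acc
from . import changes as chg
from . import classify as cls
from . import grids, indices, reporting, sampling, synthetic
from .errors import ConfigurationError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RegionSpec:
    """One synthetic study region."""

    name: str
    rows: int = 128
    cols: int = 128
    n_clearings: int = 1
    n_burns: int = 1
    patch_px: tuple[int, int] = (6, 12)


@dataclass
class PipelineConfig:
    """All scalar settings of the pipeline, with the method defaults."""

    seed: int = 0
    years: tuple[int, ...] = (2020, 2021, 2022)
    regions: list[RegionSpec] = field(
        default_factory=lambda: [RegionSpec("region-a"), RegionSpec("region-b")]
    )
    classification_window: tuple[int, int] = (4, 9)
    mosaic_window: tuple[int, int] = (6, 8)
    train_fraction: float = 0.6
    change_train_fraction: float = 0.7
    density_per_km2: float = 2.0
    buffer_m: float = 10.0
    min_dist_m: float = 20.0
    k_sigma: float = 3.0
    candidate_rule: str = "union"
    mmu_m2: float = 400.0
    n_trees: int = 100
    cloud_threshold: float = 0.65
    label_noise_rate: float = 0.25
    cloud_fraction: float = 0.05
    pixel_size: float = 10.0
    reference_points_per_class: int = 100
    verification_per_class: int = 100
    verification_shrink_m: float = 10.0

    def validate(self) -> None:
        if self.k_sigma <= 0:
            raise ConfigurationError("k_sigma must be > 0")
        for name in ("train_fraction", "change_train_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.density_per_km2 <= 0:
            raise ConfigurationError("density_per_km2 must be > 0")
        if self.mmu_m2 < 0 or self.buffer_m < 0 or self.min_dist_m < 0:
            raise ConfigurationError("areas and distances must be >= 0")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if not (0.0 <= self.label_noise_rate < 1.0):
            raise ConfigurationError("label_noise_rate must be in [0, 1)")
        if not (0.0 <= self.cloud_fraction < 1.0):
            raise ConfigurationError("cloud_fraction must be in [0, 1)")
        if self.candidate_rule not in ("union", "intersection"):
            raise ConfigurationError("candidate_rule must be union or intersection")
        if len(self.years) < 2:
            raise ConfigurationError("at least two years are required")
        if not self.regions:
            raise ConfigurationError("at least one region is required")
        for w in (self.classification_window, self.mosaic_window):
            if not (1 <= w[0] <= w[1] <= 12):
                raise ConfigurationError(f"invalid month window {w}")

    @classmethod
    def from_dict(cls, blob: dict) -> "PipelineConfig":
        blob = dict(blob)
        regions = [
            RegionSpec(**{**r, "patch_px": tuple(r.get("patch_px", (6, 12)))})
            for r in blob.pop("regions", [])
        ]
        for key in ("years", "classification_window", "mosaic_window"):
            if key in blob:
                blob[key] = tuple(blob[key])
        cfg = cls(**blob)
        if regions:
            cfg.regions = regions
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        blob = dataclasses.asdict(self)
        blob["regions"] = [dataclasses.asdict(r) for r in self.regions]
        return blob

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _region_seed(config: PipelineConfig, index: int) -> int:
    return int(
        np.random.SeedSequence([config.seed, index]).generate_state(1)[0] % (2**31)
    )


def generate_region(
    config: PipelineConfig, spec: RegionSpec
) -> tuple[synthetic.SceneConfig, dict, synthetic.SceneTruth]:
    """Build a region's scene config (with auto-placed change events) and scene."""
    index = [r.name for r in config.regions].index(spec.name)
    seed = _region_seed(config, index)
    base = synthetic.SceneConfig(
        rows=spec.rows,
        cols=spec.cols,
        pixel_size=config.pixel_size,
        years=tuple(config.years),
        rng_seed=seed,
        label_noise_rate=config.label_noise_rate,
        cloud_fraction=config.cloud_fraction,
    )
    layout = synthetic.generate_layout(base, np.random.default_rng(seed))
    events = []
    for k, year in enumerate(config.years[1:]):
        events.extend(
            synthetic.propose_change_polygons(
                layout,
                year,
                n_clearings=spec.n_clearings,
                n_burns=spec.n_burns,
                patch_px=spec.patch_px,
                rng_seed=seed + 1 + k,
            )
        )
    scene_cfg = dataclasses.replace(base, change_events=events)
    acquisitions, truth = synthetic.make_scene(scene_cfg)
    return scene_cfg, acquisitions, truth


def classify_region(
    config: PipelineConfig,
    acquisitions: dict,
    truth: synthetic.SceneTruth,
    seed: int,
) -> dict:
    """Stage 1-2 for one region: samples, forest mask, leaf-type map."""
    year0 = config.years[0]
    season_mosaic = grids.seasonal_median_mosaic(
        acquisitions[year0], window=config.classification_window, year=year0
    )
    # multi-date feature stacks, gap-filled from the seasonal median so cloud
    # masks in single dates do not punch holes in the classified maps
    stacks = [
        grids.gap_fill(a, season_mosaic)
        for a in acquisitions[year0]
        if config.classification_window[0] <= a.date.month <= config.classification_window[1]
    ]
    eroded = sampling.erode_class_regions(truth.mock_reference, config.buffer_m)
    points = sampling.draw_stratified_points(
        eroded,
        density=config.density_per_km2,
        min_dist_m=config.min_dist_m,
        rng_seed=seed,
    )
    verified, drop_report = sampling.verify_samples_spectral(points, season_mosaic)
    split = sampling.split_samples(verified, config.train_fraction, rng_seed=seed)
    train = split.subset((split.frame["role"] == "train").to_numpy())

    forest_table = cls.extract_features(stacks, train, task="forest")
    forest_model = cls.train_model(forest_table, n_trees=config.n_trees, rng_seed=seed)
    forest_mask = cls.classify_scene(stacks, forest_model)

    leaf_train = train.subset((train.frame["forest_flag"] == "forest").to_numpy())
    leaf_table = cls.extract_features(stacks, leaf_train, task="leaf_type")
    leaf_model = cls.train_model(leaf_table, n_trees=config.n_trees, rng_seed=seed)
    leaf_map = cls.classify_scene(stacks, leaf_model, within_mask=forest_mask)

    return {
        "stacks": stacks,
        "samples": split,
        "drop_report": drop_report,
        "forest_model": forest_model,
        "forest_mask": forest_mask,
        "leaf_model": leaf_model,
        "leaf_map": leaf_map,
    }


def detect_region_changes(
    config: PipelineConfig,
    acquisitions: dict,
    truth: synthetic.SceneTruth,
    forest_mask: cls.ForestMask,
    seed: int,
    change_model: cls.ClassifierModel | None,
) -> tuple[dict, cls.ClassifierModel]:
    """Stage 3 for one region: mosaics, indices, change maps per year pair.

    Trains the change model on the first year pair when none is supplied;
    otherwise applies the given model unchanged (transfer).
    """
    mosaics = {
        y: grids.seasonal_median_mosaic(acquisitions[y], config.mosaic_window, year=y)
        for y in config.years
    }
    out: dict[tuple[int, int], dict] = {}
    for y1, y2 in zip(config.years[:-1], config.years[1:]):
        ndvi_d = indices.index_difference(
            indices.ndvi(mosaics[y1]), indices.ndvi(mosaics[y2]), domain=forest_mask.mask
        )
        nbr_d = indices.index_difference(
            indices.nbr(mosaics[y1]), indices.nbr(mosaics[y2]), domain=forest_mask.mask
        )
        candidates = indices.candidate_change_mask(
            ndvi_d, nbr_d, k=config.k_sigma, rule=config.candidate_rule
        )
        stack = chg.build_feature_stack(
            mosaics[y1], mosaics[y2], ndvi_d, nbr_d, forest_mask
        )
        if change_model is None:
            areas = chg.reference_areas_from_truth(
                truth.truth_change[(y1, y2)], rng_seed=seed
            )
            ref_samples = chg.sample_reference_areas(
                areas,
                stack,
                per_class_n=config.reference_points_per_class,
                rng_seed=seed,
                train_fraction=config.change_train_fraction,
            )
            change_model = chg.train_change_model(
                ref_samples, stack, n_trees=config.n_trees, rng_seed=seed
            )
        raw = chg.classify_changes(stack, change_model, forest_mask)
        filtered = chg.mmu_filter(raw, min_area_m2=config.mmu_m2)
        out[(y1, y2)] = {
            "candidates": candidates,
            "change_map": filtered,
            "change_map_raw": raw,
        }
    return out, change_model


def assess_region(
    config: PipelineConfig,
    truth: synthetic.SceneTruth,
    forest_mask: cls.ForestMask,
    change_results: dict,
    seed: int,
) -> dict:
    """Stage 4: error matrices against synthetic truth via verification polygons."""
    year0 = config.years[0]
    woody_truth = np.isin(
        truth.truth_labels[year0].labels, list(synthetic.WOODY_CODES)
    ).astype(int)
    fmap = forest_mask.mask.astype(int)
    polys = acc.generate_verification_polygons(
        fmap,
        pixel_size=config.pixel_size,
        per_class_n=config.verification_per_class,
        shrink_m=config.verification_shrink_m,
        rng_seed=seed,
    )
    ref = acc.verify_against_truth(polys, woody_truth)
    matrices = {"forest": acc.error_matrix(fmap, ref, labels=[0, 1])}
    for pair, res in change_results.items():
        cmap = res["change_map"].classes
        tmap = truth.truth_change[pair].classes
        cpolys = acc.generate_verification_polygons(
            cmap,
            pixel_size=config.pixel_size,
            per_class_n=config.verification_per_class,
            shrink_m=0.0,  # change patches are small; shrink would empty them
            rng_seed=seed + 1,
            classes=list(chg.CHANGE_CLASSES),
        )
        cref = acc.verify_against_truth(cpolys, tmap)
        # items whose truth lies outside the year-1 woody domain assess the
        # forest mask, not the change product; exclude them here
        outside = ~cref["label"].isin(chg.CHANGE_CLASSES)
        if outside.any():
            logger.info("change verification %s: dropped %d items outside the "
                        "truth forest domain", pair, int(outside.sum()))
            cref = cref[~outside]
        matrices[f"change_{pair[0]}_{pair[1]}"] = acc.error_matrix(
            cmap, cref, labels=list(chg.CHANGE_CLASSES)
        )
    return {name: {"matrix": m, "metrics": acc.metrics(m)} for name, m in matrices.items()}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage for every region and write the artifact directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    results: dict[str, dict] = {}
    change_model: cls.ClassifierModel | None = None
    change_maps: dict[tuple[str, str], chg.ChangeMap] = {}
    forest_masks: dict[str, np.ndarray] = {}
    leaf_maps: dict[str, np.ndarray] = {}
    for index, spec in enumerate(config.regions):
        seed = _region_seed(config, index)
        logger.info("region %s: generating scene (seed %d)", spec.name, seed)
        scene_cfg, acquisitions, truth = generate_region(config, spec)
        stage1 = classify_region(config, acquisitions, truth, seed)
        change_results, change_model = detect_region_changes(
            config, acquisitions, truth, stage1["forest_mask"], seed, change_model
        )
        assessment = assess_region(
            config, truth, stage1["forest_mask"], change_results, seed
        )
        rdir = outdir / spec.name
        rdir.mkdir(exist_ok=True)
        grids.write_labels(truth.truth_labels[config.years[0]], rdir / "truth_labels.tif")
        grids.write_labels(truth.mock_reference, rdir / "mock_reference.tif")
        stage1["samples"].to_csv(rdir / "samples.csv")
        for pair, res in change_results.items():
            cmap = res["change_map"]
            grids.write_labels(
                grids.LabelRaster(
                    labels=cmap.classes,
                    pixel_size=cmap.pixel_size,
                    transform=cmap.transform,
                    code_table={k: v for k, v in cmap.code_table.items()},
                ),
                rdir / f"change_{pair[0]}_{pair[1]}.tif",
            )
            change_maps[(spec.name, f"{pair[0]}-{pair[1]}")] = cmap
        for name, entry in assessment.items():
            entry["matrix"].to_csv(rdir / f"error_matrix_{name}.csv")
        with open(rdir / "metrics.json", "w") as fh:
            json.dump(
                {name: entry["metrics"] for name, entry in assessment.items()},
                fh,
                indent=2,
            )
        forest_masks[spec.name] = stage1["forest_mask"].mask
        leaf_maps[spec.name] = stage1["leaf_map"].classes
        results[spec.name] = {
            "scene_config": scene_cfg,
            "truth": truth,
            **stage1,
            "changes": change_results,
            "assessment": assessment,
        }
    loss_table = reporting.loss_table_from_maps(change_maps, forest_masks, leaf_maps)
    report = reporting.aggregate_report(loss_table)
    report["per_region"].to_csv(outdir / "region_report.csv", index=False)
    report["pooled"].to_csv(outdir / "pooled_report.csv", index=False)
    (outdir / "summary.txt").write_text(reporting.format_summary(report) + "\n")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    results["report"] = report
    results["provenance"] = provenance
    return results
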