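"""Pixel-count-to-area conversion and regional forest-loss reporting.

Produces the per-region / per-period loss table (hectares of woody-to-
non-woody conversion and burnt forest), pooled totals across regions, class
shares, and period-over-period ratios.  Percentages are rounded half-up at
the printed precision (whole percent for class shares, one decimal for cover
fractions), the convention needed for a share of 73.51% to report as 74%.

A fixture with the published regional loss table for four Ukrainian regions
(Lviv, Kyiv, Zhytomyr, Kharkiv; periods 2020-2021 and 2021-2022) ships with
the package and is returned by :func:`load_regional_fixture`.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .changes import CHANGE_BURNT, CHANGE_WOODY, ChangeMap
from .classify import LEAF_BROADLEAVED, LEAF_CONIFEROUS
from .errors import ParameterError

logger = logging.getLogger(__name__)

LOSS_COLUMNS = [
    "region", "region_area_ha", "forest_ha", "coniferous_ha", "broadleaved_ha",
    "period", "woody_to_nonwoody_ha", "burnt_ha",
]


def area_ha(pixel_count: int, pixel_size_m: float = 10.0) -> float:
    """Hectares covered by ``pixel_count`` square pixels."""
    if pixel_count < 0:
        raise ParameterError("pixel count must be >= 0")
    return pixel_count * pixel_size_m**2 / 1e4


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    if not np.isfinite(value):
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def load_regional_fixture() -> pd.DataFrame:
    """The published per-region loss table (hectares), in tidy long form."""
    with resources.files("forestchange.data").joinpath(
        "ukraine_regional_losses.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def aggregate_report(frame: pd.DataFrame) -> dict:
    """Regional and pooled loss statistics from a tidy loss table.

    ``frame`` needs the columns in :data:`LOSS_COLUMNS`: one row per region
    and period with loss areas in hectares, plus per-region forest and area
    totals.  Returns per-region and pooled tables, with shares in percent
    (rounded half-up to the printed precision) and the period-over-period
    ratio of pooled total loss.  Regions with zero change report undefined
    (NaN) shares.
    """
    missing = [c for c in LOSS_COLUMNS if c not in frame.columns]
    if missing:
        raise ParameterError(f"loss table lacks columns {missing}")
    per = frame.copy()
    per["total_loss_ha"] = per["woody_to_nonwoody_ha"] + per["burnt_ha"]
    with np.errstate(invalid="ignore", divide="ignore"):
        woody_share = np.where(
            per["total_loss_ha"] > 0,
            100.0 * per["woody_to_nonwoody_ha"] / per["total_loss_ha"],
            np.nan,
        )
        burnt_share = np.where(
            per["total_loss_ha"] > 0,
            100.0 * per["burnt_ha"] / per["total_loss_ha"],
            np.nan,
        )
    per["woody_share_pct"] = [round_half_up(v) for v in woody_share]
    per["burnt_share_pct"] = [round_half_up(v) for v in burnt_share]
    per["loss_pct_of_forest"] = [
        round_half_up(v, 1)
        for v in 100.0 * per["total_loss_ha"] / per["forest_ha"]
    ]
    per["forest_cover_pct"] = [
        round_half_up(v, 1)
        for v in 100.0 * per["forest_ha"] / per["region_area_ha"]
    ]
    with np.errstate(invalid="ignore"):
        per["coniferous_pct_of_forest"] = [
            round_half_up(v, 1)
            for v in 100.0 * per["coniferous_ha"] / per["forest_ha"]
        ]
        per["broadleaved_pct_of_forest"] = [
            round_half_up(v, 1)
            for v in 100.0 * per["broadleaved_ha"] / per["forest_ha"]
        ]

    pooled = (
        per.groupby("period", as_index=False)[
            ["woody_to_nonwoody_ha", "burnt_ha", "total_loss_ha"]
        ]
        .sum()
        .sort_values("period")
        .reset_index(drop=True)
    )
    pooled["woody_share_pct"] = [
        round_half_up(v)
        for v in 100.0 * pooled["woody_to_nonwoody_ha"] / pooled["total_loss_ha"]
    ]
    pooled["burnt_share_pct"] = [
        round_half_up(v)
        for v in 100.0 * pooled["burnt_ha"] / pooled["total_loss_ha"]
    ]

    periods = pooled["period"].tolist()
    ratios = {}
    for earlier, later in zip(periods[:-1], periods[1:]):
        t1 = float(pooled.loc[pooled["period"] == earlier, "total_loss_ha"].iloc[0])
        t2 = float(pooled.loc[pooled["period"] == later, "total_loss_ha"].iloc[0])
        ratios[f"{later} / {earlier}"] = t2 / t1 if t1 > 0 else float("nan")

    return {
        "per_region": per,
        "pooled": pooled,
        "total_loss_ha": float(per["total_loss_ha"].sum()),
        "period_ratio": ratios,
    }


def loss_table_from_maps(
    change_maps: dict[tuple[str, str], ChangeMap],
    forest_masks: dict[str, "np.ndarray"],
    leaf_maps: dict[str, "np.ndarray"] | None = None,
    region_area_px: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build the tidy loss table from classified change maps.

    ``change_maps`` is keyed by (region, period); ``forest_masks`` by region
    (boolean grids).  Pixel counts convert to hectares via the change map's
    pixel size.  Missing leaf maps leave the leaf-type columns empty, as for
    a region where no leaf model was applied.
    """
    rows = []
    for (region, period), cmap in sorted(change_maps.items()):
        px = cmap.pixel_size
        fmask = np.asarray(forest_masks[region], dtype=bool)
        forest = area_ha(int(fmask.sum()), px)
        region_px = region_area_px.get(region) if region_area_px else fmask.size
        conif = broad = np.nan
        if leaf_maps and region in leaf_maps:
            leaf = np.asarray(leaf_maps[region])
            conif = area_ha(int((leaf == LEAF_CONIFEROUS).sum()), px)
            broad = area_ha(int((leaf == LEAF_BROADLEAVED).sum()), px)
        rows.append(
            {
                "region": region,
                "region_area_ha": area_ha(int(region_px), px),
                "forest_ha": forest,
                "coniferous_ha": conif,
                "broadleaved_ha": broad,
                "period": period,
                "woody_to_nonwoody_ha": area_ha(
                    int((cmap.classes == CHANGE_WOODY).sum()), px
                ),
                "burnt_ha": area_ha(int((cmap.classes == CHANGE_BURNT).sum()), px),
            }
        )
    return pd.DataFrame(rows, columns=LOSS_COLUMNS)


def format_summary(report: dict) -> str:
    """Human-readable text summary of an aggregated report."""
    lines = ["Forest loss summary", "==================="]
    pooled = report["pooled"]
    for _, row in pooled.iterrows():
        lines.append(
            f"{row['period']}: total {row['total_loss_ha']:,.0f} ha "
            f"(woody to non-woody {row['woody_to_nonwoody_ha']:,.0f} ha = "
            f"{row['woody_share_pct']:.0f}%, burnt {row['burnt_ha']:,.0f} ha = "
            f"{row['burnt_share_pct']:.0f}%)"
        )
    for pair, ratio in report["period_ratio"].items():
        lines.append(f"loss ratio {pair}: {ratio:.2f}")
    lines.append(f"all periods, all regions: {report['total_loss_ha']:,.0f} ha")
    return "\n".join(lines)
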