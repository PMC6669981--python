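"""Scale calibration, derived per-plant phenotypes and pot-level aggregation.

Photographs carry a ruler; the pixel length of 1 cm is read off each image
and pooled into a single calibration constant used to convert bounding-box
heights to millimetres.  Derived phenotypes are the mass:height ratio (the
"plump" index) and perimeter:area; survivorship is tracked weekly per pot.
Phenotype analysis is pot-level: means over the surviving plants in each
pot, weighted downstream by the number of survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "calibrate_scale",
    "height_mm",
    "mass_height_ratio",
    "survivorship_series",
    "aggregate_pots",
    "join_image_metrics",
]

PHENOTYPES = ("mass_mg", "height_mm", "mass_height_ratio", "gr_ratio", "perim_area")


@dataclass(frozen=True)
class Calibration:
    """Pooled pixels-per-cm scale with its standard error."""

    pixels_per_cm_mean: float
    pixels_per_cm_sem: float
    n_images: int

    def __post_init__(self):
        if self.pixels_per_cm_mean <= 0:
            raise ValueError("pixels_per_cm_mean must be positive")
        if self.pixels_per_cm_sem < 0:
            raise ValueError("pixels_per_cm_sem must be non-negative")


def calibrate_scale(per_image_px_per_cm) -> Calibration:
    """Pool per-image ruler readings into one scale constant.

    Arithmetic mean and standard error of the mean; a single reading gives
    SEM 0.
    """
    values = np.asarray(list(per_image_px_per_cm), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one pixels-per-cm reading")
    if np.any(values <= 0):
        raise ValueError("pixels-per-cm readings must be positive")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return Calibration(pixels_per_cm_mean=mean, pixels_per_cm_sem=sem, n_images=values.size)


def height_mm(bbox_height_px: float, cal: Calibration) -> float:
    """Convert a bounding-box height in pixels to millimetres."""
    return bbox_height_px / cal.pixels_per_cm_mean * 10.0


def mass_height_ratio(mass_mg: float, height_mm: float) -> float:
    """Dry mass normalized by height (mg/mm) — the "plump" index."""
    if mass_mg <= 0:
        raise ValueError("mass must be positive")
    if height_mm <= 0:
        raise ValueError("height must be positive")
    return mass_mg / height_mm


def survivorship_series(plants: pd.DataFrame) -> pd.DataFrame:
    """Per-pot weekly survivor counts and proportions.

    ``plants`` must have pot_id, block, host and alive_week_1..w boolean
    columns.  A plant counted dead must stay dead at every later week; a
    dead-to-alive transition raises.
    """
    week_cols = sorted(
        (c for c in plants.columns if c.startswith("alive_week_")),
        key=lambda c: int(c.removeprefix("alive_week_")),
    )
    if not week_cols:
        raise ValueError("no alive_week_* columns found")
    flags = plants[week_cols].to_numpy(dtype=bool)
    if np.any(~flags[:, :-1] & flags[:, 1:]):
        raise ValueError("resurrection detected: a plant flagged dead is later alive")
    counts = plants.groupby(["pot_id", "block", "host"], sort=True)[week_cols].sum()
    n_planted = plants.groupby(["pot_id", "block", "host"], sort=True).size()
    out = counts.reset_index().melt(
        id_vars=["pot_id", "block", "host"], var_name="week", value_name="n_alive"
    )
    out["week"] = out["week"].str.removeprefix("alive_week_").astype(int)
    out = out.merge(n_planted.rename("n_planted").reset_index(), on=["pot_id", "block", "host"])
    out["proportion"] = out["n_alive"] / out["n_planted"]
    return out.sort_values(["pot_id", "week"]).reset_index(drop=True)


def aggregate_pots(plants: pd.DataFrame) -> pd.DataFrame:
    """Pot-level summaries: phenotype means over survivors, weight = survivors.

    Pots with zero survivors keep their survivorship but carry missing
    phenotype means and weight 0 (they are excluded from weighted phenotype
    models downstream, retained for survivorship).
    """
    df = plants.copy()
    if "mass_height_ratio" not in df.columns and {"mass_mg", "height_mm"} <= set(df.columns):
        df["mass_height_ratio"] = df["mass_mg"] / df["height_mm"]
    pheno_cols = [c for c in PHENOTYPES if c in df.columns]
    grouped = df.groupby(["pot_id", "block", "host"], sort=True)
    out = grouped.agg(n_planted=("plant_id", "size"), n_survivors=("alive_final", "sum"))
    survivors = df[df["alive_final"]]
    means = survivors.groupby(["pot_id", "block", "host"], sort=True)[pheno_cols].mean()
    out = out.join(means)
    out = out.reset_index()
    out["survivorship"] = out["n_survivors"] / out["n_planted"]
    out["weight"] = out["n_survivors"]
    return out


def join_image_metrics(
    plants: pd.DataFrame,
    rois: pd.DataFrame,
    color: pd.DataFrame | None,
    cal: Calibration,
) -> pd.DataFrame:
    """Join per-image ROI morphometrics (and color) onto the plant table.

    ROI rows must carry an ``image`` column naming the pot (one photograph
    per pot) and are ordered left-to-right within each image, matching the
    planting order of that pot's surviving plants.  Image-derived height
    replaces the tabular height; perimeter:area is attached per plant.
    """
    img = rois.copy()
    if color is not None:
        img = img.merge(color, on=["image", "roi_id"], how="left", suffixes=("", "_color"))
    img["rank"] = img.groupby("image")["centroid_c"].rank(method="first").astype(int)
    img["height_img_mm"] = height_mm(img["bbox_height_px"], cal)
    img["perim_area"] = img["perimeter_px"] / img["area_px2"]
    keep = ["pot_id", "rank", "height_img_mm", "area_px2", "perimeter_px", "perim_area"]
    img = img.rename(columns={"image": "pot_id"})
    if color is not None and "gr_ratio" in img.columns:
        img = img.rename(columns={"gr_ratio": "gr_ratio_img"})
        keep.append("gr_ratio_img")
    img = img[keep]

    out = plants.copy()
    surv = out["alive_final"].fillna(False).astype(bool)
    out["rank"] = np.nan
    ranks = out[surv].sort_values("plant_id").groupby("pot_id").cumcount() + 1
    out.loc[ranks.index, "rank"] = ranks
    out = out.merge(img, on=["pot_id", "rank"], how="left").drop(columns=["rank"])
    # image-derived measurements replace the tabular twins where available
    if "height_mm" in out.columns:
        out = out.rename(columns={"height_mm": "height_tab_mm"})
    out["height_mm"] = out["height_img_mm"].fillna(out.get("height_tab_mm"))
    out = out.drop(columns=["height_img_mm"])
    if "gr_ratio_img" in out.columns:
        if "gr_ratio" in out.columns:
            out = out.rename(columns={"gr_ratio": "gr_ratio_tab"})
        out = out.rename(columns={"gr_ratio_img": "gr_ratio"})
    out["mass_height_ratio"] = out["mass_mg"] / out["height_mm"]
    return out
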