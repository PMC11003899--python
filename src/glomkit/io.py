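"""Readers and writers for the pipeline's file formats.

Tables are plain CSV (comma-separated, UTF-8, ``.`` decimal, mandatory
header); images are 8-bit RGB TIFF or PNG; region masks are indexed PNG with
labels 0 = background, 1 = cortex, 2 = medulla. Booleans are written as 0/1.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .morphometry import IndividualMetrics, SlideMetrics
from .segmentation import DetectedObject, RegionMask, SlideImage
from .synthetic import EXCLUSION_ORDER, GroundTruth, SubjectRecord

__all__ = [
    "SchemaError",
    "OBJECT_COLUMNS",
    "write_object_csv",
    "read_object_csv",
    "write_region_mask",
    "read_region_mask",
    "write_slide_image",
    "read_slide_image",
    "write_ground_truth_csv",
    "read_ground_truth_points",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_slide_metrics_csv",
    "write_individual_metrics_csv",
    "write_validation_csv",
]


class SchemaError(ValueError):
    """A table is missing required columns or holds malformed rows."""


OBJECT_COLUMNS = [
    "object_id",
    "slide_id",
    "kidney_side",
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "perimeter_um",
    "excluded",
    "exclusion_reason",
]

GROUND_TRUTH_COLUMNS = [
    "id",
    "cx_um",
    "cy_um",
    "axis_a_um",
    "axis_b_um",
    "area_um2",
    "perimeter_um",
]

COHORT_COLUMNS = [
    "id",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "bmi",
    "bsa_m2",
    "kidney_weight_g",
    "kidney_length_cm",
    "smoker",
    "chronic_alcohol",
    "blood_alcohol",
    *[f"flag_{name}" for name in EXCLUSION_ORDER],
]

SLIDE_METRIC_COLUMNS = [
    "slide_id",
    "kidney_side",
    "n_glomeruli",
    "cortex_area_mm2",
    "gd_per_mm2",
    "mean_area_um2",
    "sd_area_um2",
    "mean_perimeter_um",
    "gv_mm3",
    "vgd_per_mm3",
    "total_glom_area_mm2",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_object_csv(
    path: str | Path,
    objects: Sequence[DetectedObject],
    slide_id: str = "slide",
    kidney_side: str = "left",
) -> Path:
    path = Path(path)
    rows = [
        {
            "object_id": o.object_id,
            "slide_id": slide_id,
            "kidney_side": kidney_side,
            "centroid_x_um": o.centroid_um[0],
            "centroid_y_um": o.centroid_um[1],
            "area_um2": o.area_um2,
            "perimeter_um": o.perimeter_um,
            "excluded": int(o.excluded),
            "exclusion_reason": o.exclusion_reason,
        }
        for o in objects
    ]
    pd.DataFrame(rows, columns=OBJECT_COLUMNS).to_csv(path, index=False)
    return path


def read_object_csv(path: str | Path) -> list[DetectedObject]:
    """Read a per-object CSV back into detected objects.

    Pixel counts are not serialized, so re-read objects carry
    ``pixel_count=None``. Malformed rows are rejected with their line number
    (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, OBJECT_COLUMNS, path)
    objects: list[DetectedObject] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            objects.append(
                DetectedObject(
                    object_id=int(row["object_id"]),
                    centroid_um=(float(row["centroid_x_um"]), float(row["centroid_y_um"])),
                    area_um2=float(row["area_um2"]),
                    perimeter_um=float(row["perimeter_um"]),
                    pixel_count=None,
                    excluded=bool(int(row["excluded"])),
                    exclusion_reason=str(row["exclusion_reason"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed row at line {line}: {exc}") from exc
    return objects


_MASK_PALETTE = [255, 255, 255, 230, 170, 185, 185, 140, 200]  # bg, cortex, medulla


def write_region_mask(path: str | Path, mask: RegionMask) -> Path:
    path = Path(path)
    img = Image.fromarray(mask.labels, mode="P")
    img.putpalette(_MASK_PALETTE + [0] * (768 - len(_MASK_PALETTE)))
    img.save(path, format="PNG")
    return path


def read_region_mask(path: str | Path, mpp: float) -> RegionMask:
    labels = np.asarray(Image.open(path), dtype=np.uint8)
    return RegionMask(labels=labels, mpp=mpp)


def write_slide_image(path: str | Path, image: SlideImage) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        Image.fromarray(image.pixels, mode="RGB").save(path)
    return path


def read_slide_image(
    path: str | Path,
    mpp: float,
    slide_id: str | None = None,
    kidney_side: str = "left",
    stain_level: str | None = None,
) -> SlideImage:
    """Read a TIFF/PNG slide; the physical scale must be supplied."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(
        pixels=np.ascontiguousarray(pixels, dtype=np.uint8),
        mpp=mpp,
        slide_id=slide_id or path.stem,
        kidney_side=kidney_side,
        stain_level=stain_level,
    )


def write_ground_truth_csv(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    rows = [
        {
            "id": g.glom_id,
            "cx_um": g.cx_um,
            "cy_um": g.cy_um,
            "axis_a_um": g.axis_a_um,
            "axis_b_um": g.axis_b_um,
            "area_um2": g.area_um2,
            "perimeter_um": g.perimeter_um,
        }
        for g in truth.glomeruli
    ]
    pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS).to_csv(path, index=False)
    return path


def read_ground_truth_points(path: str | Path) -> list[tuple[float, float]]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["cx_um", "cy_um"], path)
    return list(zip(df["cx_um"].astype(float), df["cy_um"].astype(float)))


def write_cohort_csv(path: str | Path, records: Sequence[SubjectRecord]) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "sex": r.sex,
            "age": r.age,
            "height_cm": r.height_cm,
            "weight_kg": r.weight_kg,
            "bmi": r.bmi,
            "bsa_m2": r.bsa_m2,
            "kidney_weight_g": r.kidney_weight_g,
            "kidney_length_cm": r.kidney_length_cm,
            "smoker": int(r.smoker),
            "chronic_alcohol": int(r.chronic_alcohol),
            "blood_alcohol": int(r.blood_alcohol),
        }
        for name in EXCLUSION_ORDER:
            row[f"flag_{name}"] = int(r.exclusion_flags.get(name, False))
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    records: list[SubjectRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            records.append(
                SubjectRecord(
                    id=str(row["id"]),
                    sex=str(row["sex"]),
                    age=float(row["age"]),
                    height_cm=float(row["height_cm"]),
                    weight_kg=float(row["weight_kg"]),
                    bmi=float(row["bmi"]),
                    bsa_m2=float(row["bsa_m2"]),
                    kidney_weight_g=float(row["kidney_weight_g"]),
                    kidney_length_cm=float(row["kidney_length_cm"]),
                    smoker=bool(int(row["smoker"])),
                    chronic_alcohol=bool(int(row["chronic_alcohol"])),
                    blood_alcohol=bool(int(row["blood_alcohol"])),
                    exclusion_flags={
                        name: bool(int(row[f"flag_{name}"])) for name in EXCLUSION_ORDER
                    },
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed row at line {line}: {exc}") from exc
    return records


def _metric_row(m: SlideMetrics) -> dict:
    return {
        "slide_id": m.slide_id,
        "kidney_side": m.kidney_side,
        "n_glomeruli": m.n_glomeruli,
        "cortex_area_mm2": m.cortex_area_mm2,
        "gd_per_mm2": m.gd_per_mm2,
        "mean_area_um2": m.mean_area_um2,
        "sd_area_um2": m.sd_area_um2,
        "mean_perimeter_um": m.mean_perimeter_um,
        "gv_mm3": m.gv_mm3,
        "vgd_per_mm3": m.vgd_per_mm3,
        "total_glom_area_mm2": m.total_glom_area_mm2,
    }


def write_slide_metrics_csv(path: str | Path, metrics: Sequence[SlideMetrics]) -> Path:
    path = Path(path)
    pd.DataFrame([_metric_row(m) for m in metrics], columns=SLIDE_METRIC_COLUMNS).to_csv(
        path, index=False
    )
    return path


def write_individual_metrics_csv(
    path: str | Path, individuals: Sequence[IndividualMetrics]
) -> Path:
    path = Path(path)
    rows = [
        {
            "id": ind.id,
            "total_count": ind.total_count,
            "mean_count": ind.mean_count,
            "mean_gd": ind.mean_gd,
            "mean_area_um2": ind.mean_area_um2,
            "mean_perimeter_um": ind.mean_perimeter_um,
            "mean_gv_mm3": ind.mean_gv_mm3,
            "single_side": int(ind.single_side),
        }
        for ind in individuals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_validation_csv(path: str | Path, rows: Sequence[dict]) -> Path:
    """Validation report: one row per slide with counts and FP/FN percentages."""
    path = Path(path)
    cols = [
        "slide_id",
        "n_reference",
        "n_algorithm",
        "n_fp",
        "n_fn",
        "fp_percent",
        "fn_percent",
    ]
    pd.DataFrame(list(rows), columns=cols).to_csv(path, index=False)
    return path
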