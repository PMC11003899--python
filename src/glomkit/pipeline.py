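"""End-to-end orchestration: generator → segmentation → morphometry →
validation → cohort statistics, with logging, manifests and reports.

A run is fully determined by its :class:`RunConfig` (including the seed);
rerunning with an identical config reproduces byte-identical metric CSVs.
Per-slide failures are logged and skipped so one bad section does not void
a cohort run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .morphometry import (
    CohortSummary,
    IndividualMetrics,
    SlideMetrics,
    aggregate_individual,
    cohort_summary,
    slide_metrics,
)
from .segmentation import (
    DetectedObject,
    RegionMask,
    SlideImage,
    classify_tissue,
    clean_objects,
    detect_glomeruli,
    segment_cortex_medulla,
    standardize_resolution,
)
from .stats import (
    chi_squared_test,
    compare_by_median_split,
    compare_groups,
    regression_strategy,
)
from .synthetic import (
    GroundTruth,
    SlideSpec,
    SubjectRecord,
    eligibility_filter,
    generate_cohort,
    generate_slide,
)
from .validation import MatchResult, error_rates, match_objects

__all__ = ["RunConfig", "RunResult", "run_pipeline", "process_slide", "SlideInput"]

log = logging.getLogger("glomkit")


@dataclass(frozen=True)
class SlideInput:
    """One externally supplied slide image for ``images`` mode."""

    path: str
    mpp: float | None
    individual_id: str
    kidney_side: str = "left"
    slide_id: str | None = None


@dataclass
class RunConfig:
    """Everything that determines one pipeline run."""

    out_dir: str | Path = "glomkit_run"
    mode: str = "synthetic"  # "synthetic" | "images"
    n_male: int = 54
    n_female: int = 32
    slide_width_px: int = 1200
    slide_height_px: int = 1200
    slide_mpp: float = 2.0
    cortex_fraction: float = 0.7
    target_mpp: float = 2.0
    min_object_um2: float = 40.0
    area_floor_um2: float = 10_000.0
    seed: int = 0
    write_images: bool = False
    run_stats: bool = True
    images: tuple[SlideInput, ...] = ()

    def validate(self) -> None:
        if self.mode not in ("synthetic", "images"):
            raise ValueError("mode must be 'synthetic' or 'images'")
        for name in ("target_mpp", "min_object_um2", "area_floor_um2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.mode == "images":
            for entry in self.images:
                if entry.mpp is None or not entry.mpp > 0:
                    raise ValueError(f"image {entry.path}: missing mpp metadata")


@dataclass
class RunResult:
    config: RunConfig
    slide_metrics: list[SlideMetrics]
    individuals: list[IndividualMetrics]
    summary: CohortSummary | None
    validation: list[dict]
    cohort: list[SubjectRecord]
    manifest: dict[str, str]
    out_dir: Path
    failures: list[str] = field(default_factory=list)


def process_slide(
    image: SlideImage,
    target_mpp: float = 2.0,
    min_object_um2: float = 40.0,
    area_floor_um2: float = 10_000.0,
) -> tuple[SlideMetrics, list[DetectedObject], list[DetectedObject], RegionMask]:
    """Run the full per-slide chain and return metrics + kept/excluded objects."""
    image = standardize_resolution(image, target_mpp)
    tissue = classify_tissue(image)
    regions = segment_cortex_medulla(image, tissue)
    objects = detect_glomeruli(image, regions, min_object_um2=min_object_um2)
    kept, excluded = clean_objects(objects, area_floor_um2=area_floor_um2)
    metrics = slide_metrics(
        kept,
        regions.cortex_area_mm2,
        slide_id=image.slide_id,
        kidney_side=image.kidney_side,
    )
    return metrics, kept, excluded, regions


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _stats_reports(
    out_dir: Path,
    cohort: Sequence[SubjectRecord],
    individuals: Sequence[IndividualMetrics],
    lines: list[str],
) -> list[Path]:
    """Sex comparisons, categorical tests, median-split table and regression."""
    by_id = {ind.id: ind for ind in individuals}
    rows = []
    for rec in cohort:
        ind = by_id.get(rec.id)
        if ind is None:
            continue
        rows.append(
            {
                "id": rec.id,
                "sex": rec.sex,
                "female": int(rec.sex == "female"),
                "age": rec.age,
                "height_cm": rec.height_cm,
                "weight_kg": rec.weight_kg,
                "bmi": rec.bmi,
                "bsa_m2": rec.bsa_m2,
                "kidney_weight_g": rec.kidney_weight_g,
                "smoker": int(rec.smoker),
                "chronic_alcohol": int(rec.chronic_alcohol),
                "blood_alcohol": int(rec.blood_alcohol),
                "total_count": ind.total_count,
                "mean_count": ind.mean_count,
                "mean_gd": ind.mean_gd,
                "mean_area_um2": ind.mean_area_um2,
                "mean_perimeter_um": ind.mean_perimeter_um,
                "mean_gv_mm3": ind.mean_gv_mm3,
            }
        )
    df = pd.DataFrame(rows)
    written: list[Path] = []
    men = df[df["sex"] == "male"]
    women = df[df["sex"] == "female"]
    if len(men) < 3 or len(women) < 3:
        lines.append("stats: skipped (fewer than 3 subjects in a sex group)")
        return written

    def sex_table(variables: Sequence[str], name: str) -> Path:
        out = []
        for var in variables:
            res = compare_groups(
                men[var].to_numpy(),
                women[var].to_numpy(),
                variable=var,
                labels=("male", "female"),
            )
            lines.append(
                f"{name}/{var}: shapiro_p=({res.normality[0].shapiro_p:.3g},"
                f"{res.normality[1].shapiro_p:.3g}) skew=({res.normality[0].skewness:.2f},"
                f"{res.normality[1].skewness:.2f}) -> {res.test_used} p={res.p_value:.3g}"
            )
            out.append(
                {
                    "variable": var,
                    "male_mean": res.mean_sd[0][0],
                    "male_sd": res.mean_sd[0][1],
                    "female_mean": res.mean_sd[1][0],
                    "female_sd": res.mean_sd[1][1],
                    "test": res.test_used,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        path = out_dir / name
        pd.DataFrame(out).to_csv(path, index=False)
        return path

    written.append(
        sex_table(
            ["age", "height_cm", "weight_kg", "bmi", "bsa_m2", "kidney_weight_g"],
            "stats_population_by_sex.csv",
        )
    )
    written.append(
        sex_table(
            [
                "total_count",
                "mean_count",
                "mean_gd",
                "mean_area_um2",
                "mean_perimeter_um",
                "mean_gv_mm3",
            ],
            "stats_morphometry_by_sex.csv",
        )
    )

    # categorical traits by sex
    cat_rows = []
    for var in ("smoker", "blood_alcohol", "chronic_alcohol"):
        table = [
            [int(men[var].sum()), int(len(men) - men[var].sum())],
            [int(women[var].sum()), int(len(women) - women[var].sum())],
        ]
        try:
            res = chi_squared_test(table)
            cat_rows.append(
                {
                    "variable": var,
                    "male_yes": table[0][0],
                    "male_no": table[0][1],
                    "female_yes": table[1][0],
                    "female_no": table[1][1],
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
            lines.append(f"chi2/{var}: stat={res.statistic:.3g} p={res.p_value:.3g}")
        except ValueError as exc:
            lines.append(f"chi2/{var}: skipped ({exc})")
    path = out_dir / "stats_categorical_by_sex.csv"
    pd.DataFrame(cat_rows).to_csv(path, index=False)
    written.append(path)

    # median split on GD, overall and within sex
    try:
        split = compare_by_median_split(
            df,
            split_key="mean_gd",
            variables=["age", "bmi", "bsa_m2", "kidney_weight_g", "mean_area_um2"],
            by_sex=True,
        )
        split_rows = []
        for stratum, table in split.items():
            for var, res in table.items():
                split_rows.append(
                    {
                        "stratum": stratum,
                        "variable": var,
                        "low_mean": res.mean_sd[0][0],
                        "low_sd": res.mean_sd[0][1],
                        "high_mean": res.mean_sd[1][0],
                        "high_sd": res.mean_sd[1][1],
                        "test": res.test_used,
                        "p_value": res.p_value,
                    }
                )
                lines.append(
                    f"median_split/{stratum}/{var}: {res.test_used} p={res.p_value:.3g}"
                )
        path = out_dir / "stats_median_split.csv"
        pd.DataFrame(split_rows).to_csv(path, index=False)
        written.append(path)
    except ValueError as exc:
        lines.append(f"median_split: skipped ({exc})")

    # univariate screen + fully adjusted regression on GD
    try:
        reg = regression_strategy(
            df,
            outcome="mean_gd",
            covariates=[
                "female",
                "age",
                "bmi",
                "height_cm",
                "kidney_weight_g",
                "mean_area_um2",
            ],
        )
        reg_rows = []
        for eff in reg.effects:
            row = {
                "covariate": eff.name,
                "beta": eff.unadjusted.beta,
                "ci_low": eff.unadjusted.ci_low,
                "ci_high": eff.unadjusted.ci_high,
                "p_value": eff.unadjusted.p_value,
                "adjusted_beta": math.nan,
                "adjusted_ci_low": math.nan,
                "adjusted_ci_high": math.nan,
                "adjusted_p_value": math.nan,
            }
            if eff.adjusted is not None:
                row.update(
                    adjusted_beta=eff.adjusted.beta,
                    adjusted_ci_low=eff.adjusted.ci_low,
                    adjusted_ci_high=eff.adjusted.ci_high,
                    adjusted_p_value=eff.adjusted.p_value,
                )
            reg_rows.append(row)
        path = out_dir / "stats_regression.csv"
        pd.DataFrame(reg_rows).to_csv(path, index=False)
        written.append(path)
        lines.append(
            f"regression: selected={list(reg.selected)} "
            f"log_transformed={reg.log_transformed} "
            f"residual_shapiro_p={reg.residual_shapiro_p}"
        )
    except (ValueError, KeyError) as exc:
        lines.append(f"regression: skipped ({exc})")
    return written


def _iter_synthetic_slides(cohort: Sequence[SubjectRecord]):
    for rec in cohort:
        for side in ("left", "right"):
            spec: SlideSpec | None = getattr(rec, f"slide_{side}")
            if spec is not None:
                yield rec, side, spec


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute a full run and write all artifacts under ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out_dir)
    artifacts: list[Path] = []
    failures: list[str] = []
    stats_lines: list[str] = []
    try:
        cfg_path = out_dir / "config.json"
        cfg_dict = dataclasses.asdict(config)
        cfg_dict["out_dir"] = str(config.out_dir)
        cfg_path.write_text(json.dumps(cfg_dict, indent=2, default=str))
        artifacts.append(cfg_path)
        log.info("run started; mode=%s seed=%d", config.mode, config.seed)

        all_metrics: list[SlideMetrics] = []
        per_individual: dict[str, dict[str, SlideMetrics]] = {}
        validation_rows: list[dict] = []
        object_rows: list[DetectedObject] = []
        object_meta: list[tuple[str, str]] = []

        if config.mode == "synthetic":
            template = SlideSpec(
                width_px=config.slide_width_px,
                height_px=config.slide_height_px,
                mpp=config.slide_mpp,
                cortex_fraction=config.cortex_fraction,
            )
            cohort = generate_cohort(
                n_male=config.n_male,
                n_female=config.n_female,
                seed=config.seed,
                slide_template=template,
            )
            cohort, _ = eligibility_filter(cohort)
            slides = list(_iter_synthetic_slides(cohort))
        else:
            cohort = []
            slides = list(config.images)

        for item in slides:
            if config.mode == "synthetic":
                rec, side, spec = item
                slide_id = f"{rec.id}_{side[0].upper()}"
                try:
                    image, truth = generate_slide(
                        spec, slide_id=slide_id, kidney_side=side
                    )
                except Exception as exc:  # noqa: BLE001 - per-slide isolation
                    log.error("slide %s: generation failed: %s", slide_id, exc)
                    failures.append(slide_id)
                    continue
                individual_id = rec.id
            else:
                entry = item
                slide_id = entry.slide_id or Path(entry.path).stem
                side = entry.kidney_side
                individual_id = entry.individual_id
                truth = None
                try:
                    image = gio.read_slide_image(
                        entry.path, mpp=entry.mpp, slide_id=slide_id, kidney_side=side
                    )
                except Exception as exc:  # noqa: BLE001
                    log.error("slide %s: read failed: %s", slide_id, exc)
                    failures.append(slide_id)
                    continue

            try:
                metrics, kept, excluded, regions = process_slide(
                    image,
                    target_mpp=config.target_mpp,
                    min_object_um2=config.min_object_um2,
                    area_floor_um2=config.area_floor_um2,
                )
            except Exception as exc:  # noqa: BLE001
                log.error("slide %s: processing failed: %s", slide_id, exc)
                failures.append(slide_id)
                continue

            log.info(
                "slide %s: detected=%d kept=%d excluded=%d cortex_mm2=%.3f",
                slide_id,
                len(kept) + len(excluded),
                len(kept),
                len(excluded),
                metrics.cortex_area_mm2,
            )
            all_metrics.append(metrics)
            per_individual.setdefault(individual_id, {})[side] = metrics
            for obj in [*kept, *excluded]:
                object_rows.append(obj)
                object_meta.append((slide_id, side))

            if truth is not None:
                match = match_objects(kept, truth)
                if match.n_reference > 0:
                    fp, fn = error_rates(match)
                else:
                    fp, fn = 0.0, 0.0
                validation_rows.append(
                    {
                        "slide_id": slide_id,
                        "n_reference": match.n_reference,
                        "n_algorithm": match.n_algorithm,
                        "n_fp": match.n_false_positive,
                        "n_fn": match.n_false_negative,
                        "fp_percent": fp,
                        "fn_percent": fn,
                    }
                )
            if config.write_images:
                artifacts.append(
                    gio.write_slide_image(out_dir / f"{slide_id}.png", image)
                )
                artifacts.append(
                    gio.write_region_mask(out_dir / f"{slide_id}_mask.png", regions)
                )

        individuals = [
            aggregate_individual(
                sides.get("left"), sides.get("right"), individual_id=iid
            )
            for iid, sides in per_individual.items()
        ]
        summary = cohort_summary(individuals) if individuals else None

        # tabular artifacts
        obj_path = out_dir / "objects.csv"
        rows = []
        for obj, (sid, side) in zip(object_rows, object_meta):
            rows.append(
                {
                    "object_id": obj.object_id,
                    "slide_id": sid,
                    "kidney_side": side,
                    "centroid_x_um": obj.centroid_um[0],
                    "centroid_y_um": obj.centroid_um[1],
                    "area_um2": obj.area_um2,
                    "perimeter_um": obj.perimeter_um,
                    "excluded": int(obj.excluded),
                    "exclusion_reason": obj.exclusion_reason,
                }
            )
        pd.DataFrame(rows, columns=gio.OBJECT_COLUMNS).to_csv(obj_path, index=False)
        artifacts.append(obj_path)
        artifacts.append(gio.write_slide_metrics_csv(out_dir / "slide_metrics.csv", all_metrics))
        artifacts.append(
            gio.write_individual_metrics_csv(out_dir / "individual_metrics.csv", individuals)
        )
        if validation_rows:
            artifacts.append(gio.write_validation_csv(out_dir / "validation.csv", validation_rows))
        if cohort:
            artifacts.append(gio.write_cohort_csv(out_dir / "cohort.csv", cohort))
        if summary is not None:
            sum_path = out_dir / "cohort_summary.csv"
            pd.DataFrame([dataclasses.asdict(summary)]).to_csv(sum_path, index=False)
            artifacts.append(sum_path)

        if config.run_stats and cohort and individuals:
            artifacts.extend(_stats_reports(out_dir, cohort, individuals, stats_lines))
        (out_dir / "analysis_log.txt").write_text("\n".join(stats_lines) + "\n")

        manifest = {p.name: _sha256(p) for p in artifacts if p.exists()}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info(
            "run finished: %d slides, %d individuals, %d failures",
            len(all_metrics),
            len(individuals),
            len(failures),
        )
    finally:
        log.removeHandler(handler)
        handler.close()

    return RunResult(
        config=config,
        slide_metrics=all_metrics,
        individuals=individuals,
        summary=summary,
        validation=validation_rows,
        cohort=list(cohort),
        manifest=manifest,
        out_dir=out_dir,
        failures=failures,
    )
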