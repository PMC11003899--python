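"""Stereological morphometry: glomerular density, size, and volume.

Quantities follow the standard autopsy-morphometry conventions:

- glomerular density GD = n / A, glomeruli per mm² of cortex;
- mean glomerular volume by the Weibel-Gomez estimator
  GV = (1.382 · Ā^{3/2}) / 1.01, with Ā the mean profile area, the shape
  coefficient 1.382 (spheres) and the size-distribution correction 1.01;
- volumetric glomerular density
  VGD = (1/1.382) · sqrt((n/A)³ / (S/A)), glomeruli per mm³, with S the total
  glomerular profile area.

Object areas are carried in µm² and cortex areas in mm² (the units the
quantities are conventionally reported in); the single conversion constant is
10⁶ µm²/mm². Size statistics over an empty slide are represented as NaN,
never 0, so they cannot corrupt cohort means.

The algebraic identity VGD × GV = (S/A) / 1.01 (when GV is evaluated at
Ā = S/n) holds exactly and is enforced in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .segmentation import DetectedObject

__all__ = [
    "SHAPE_COEFFICIENT",
    "SIZE_DISTRIBUTION_CORRECTION",
    "SlideMetrics",
    "IndividualMetrics",
    "CohortSummary",
    "slide_metrics",
    "weibel_gomez_volume",
    "volumetric_density",
    "aggregate_individual",
    "cohort_summary",
    "median_confidence_interval",
]

SHAPE_COEFFICIENT = 1.382
SIZE_DISTRIBUTION_CORRECTION = 1.01
UM2_PER_MM2 = 1e6
UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class SlideMetrics:
    """Morphometry of one slide (one kidney section)."""

    slide_id: str
    kidney_side: str
    n_glomeruli: int
    cortex_area_mm2: float
    gd_per_mm2: float
    mean_area_um2: float  # NaN when n = 0
    sd_area_um2: float
    mean_perimeter_um: float
    gv_mm3: float
    vgd_per_mm3: float
    total_glom_area_mm2: float


@dataclass(frozen=True)
class IndividualMetrics:
    """Per-individual aggregation over the left and right kidney slides."""

    id: str
    left: SlideMetrics | None
    right: SlideMetrics | None
    mean_gd: float
    total_count: int
    mean_count: float
    mean_area_um2: float
    mean_perimeter_um: float
    mean_gv_mm3: float
    single_side: bool = False


def weibel_gomez_volume(mean_area_um2: float) -> float:
    """Mean glomerular volume (mm³) from mean profile area (µm²)."""
    if mean_area_um2 < 0:
        raise ValueError("mean area must be non-negative")
    if math.isnan(mean_area_um2):
        return math.nan
    gv_um3 = SHAPE_COEFFICIENT * mean_area_um2**1.5 / SIZE_DISTRIBUTION_CORRECTION
    return gv_um3 / UM3_PER_MM3


def volumetric_density(
    n_glomeruli: float, cortex_area_mm2: float, total_glom_area_mm2: float
) -> float:
    """Volumetric glomerular density (glomeruli / mm³ of cortex).

    VGD = (1/1.382) · sqrt((n/A)³ / (S/A)); invariant under joint rescaling
    of n, A and S.
    """
    if cortex_area_mm2 <= 0:
        raise ValueError("cortex area must be positive")
    if total_glom_area_mm2 <= 0:
        if n_glomeruli > 0:
            raise ValueError("total glomerular area must be positive when n > 0")
        return 0.0
    na = n_glomeruli / cortex_area_mm2
    sa = total_glom_area_mm2 / cortex_area_mm2
    return math.sqrt(na**3 / sa) / SHAPE_COEFFICIENT


def slide_metrics(
    kept: Sequence[DetectedObject],
    cortex_area_mm2: float,
    slide_id: str = "slide",
    kidney_side: str = "left",
) -> SlideMetrics:
    """Summarize kept (cleaned) objects on one slide.

    A slide with glomeruli but no measurable cortex is an inconsistent input
    and raises; an empty slide yields GD 0 with NaN size statistics.
    """
    n = len(kept)
    if cortex_area_mm2 < 0:
        raise ValueError("cortex area must be non-negative")
    if cortex_area_mm2 == 0 and n > 0:
        raise ValueError("glomeruli outside measurable cortex")
    if n == 0:
        return SlideMetrics(
            slide_id=slide_id,
            kidney_side=kidney_side,
            n_glomeruli=0,
            cortex_area_mm2=cortex_area_mm2,
            gd_per_mm2=0.0,
            mean_area_um2=math.nan,
            sd_area_um2=math.nan,
            mean_perimeter_um=math.nan,
            gv_mm3=math.nan,
            vgd_per_mm3=math.nan,
            total_glom_area_mm2=0.0,
        )
    areas = np.array([o.area_um2 for o in kept], dtype=np.float64)
    perims = np.array([o.perimeter_um for o in kept], dtype=np.float64)
    total_mm2 = float(areas.sum()) / UM2_PER_MM2
    mean_area = float(areas.mean())
    return SlideMetrics(
        slide_id=slide_id,
        kidney_side=kidney_side,
        n_glomeruli=n,
        cortex_area_mm2=cortex_area_mm2,
        gd_per_mm2=n / cortex_area_mm2,
        mean_area_um2=mean_area,
        sd_area_um2=float(areas.std(ddof=1)) if n > 1 else 0.0,
        mean_perimeter_um=float(perims.mean()),
        gv_mm3=weibel_gomez_volume(mean_area),
        vgd_per_mm3=volumetric_density(n, cortex_area_mm2, total_mm2),
        total_glom_area_mm2=total_mm2,
    )


def _nanmean_pair(a: float, b: float) -> float:
    vals = [v for v in (a, b) if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def aggregate_individual(
    left: SlideMetrics | None,
    right: SlideMetrics | None,
    individual_id: str | None = None,
) -> IndividualMetrics:
    """Combine the two kidney slides of one individual.

    The individual's GD is the mean of the two per-kidney GDs; the total
    count is the sum over both slides and the mean count is half the total.
    If only one side is available, its values stand in and the result is
    flagged ``single_side``.
    """
    if left is None and right is None:
        raise ValueError("at least one side is required")
    single = left is None or right is None
    sides = [m for m in (left, right) if m is not None]
    total = sum(m.n_glomeruli for m in sides)

    def pair(attr: str) -> float:
        return _nanmean_pair(
            getattr(left, attr) if left is not None else math.nan,
            getattr(right, attr) if right is not None else math.nan,
        )

    return IndividualMetrics(
        id=individual_id or sides[0].slide_id,
        left=left,
        right=right,
        mean_gd=float(np.mean([m.gd_per_mm2 for m in sides])),
        total_count=total,
        mean_count=total / len(sides),
        mean_area_um2=pair("mean_area_um2"),
        mean_perimeter_um=pair("mean_perimeter_um"),
        mean_gv_mm3=pair("gv_mm3"),
        single_side=single,
    )


def median_confidence_interval(
    values: Sequence[float], confidence: float = 0.95
) -> tuple[float, float]:
    """Distribution-free CI for the median via binomial order statistics."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    alpha = 1.0 - confidence
    j = int(binom.ppf(alpha / 2.0, n, 0.5))
    k = int(binom.ppf(1.0 - alpha / 2.0, n, 0.5))
    return float(x[max(j, 0)]), float(x[min(k, n - 1)])


@dataclass(frozen=True)
class CohortSummary:
    """Whole-cohort counting and density summary."""

    n_individuals: int
    total_glomeruli: int
    mean_per_individual: float
    sd_per_individual: float
    mean_per_kidney: float
    sd_per_kidney: float
    min_per_kidney: float
    max_per_kidney: float
    mean_gd: float
    sd_gd: float
    min_gd: float
    max_gd: float
    median_gd: float
    median_gd_ci: tuple[float, float]


def cohort_summary(individuals: Sequence[IndividualMetrics]) -> CohortSummary:
    """Totals, per-individual and per-kidney means, and the GD median CI."""
    if not individuals:
        raise ValueError("cohort is empty")
    totals = np.array([ind.total_count for ind in individuals], dtype=np.float64)
    per_kidney = np.array(
        [
            m.n_glomeruli
            for ind in individuals
            for m in (ind.left, ind.right)
            if m is not None
        ],
        dtype=np.float64,
    )
    gds = np.array([ind.mean_gd for ind in individuals], dtype=np.float64)
    n = len(individuals)
    total = int(totals.sum())
    ci = median_confidence_interval(gds) if n >= 2 else (gds[0], gds[0])
    return CohortSummary(
        n_individuals=n,
        total_glomeruli=total,
        mean_per_individual=total / n,
        sd_per_individual=float(totals.std(ddof=1)) if n > 1 else 0.0,
        mean_per_kidney=float(per_kidney.mean()),
        sd_per_kidney=float(per_kidney.std(ddof=1)) if per_kidney.size > 1 else 0.0,
        min_per_kidney=float(per_kidney.min()),
        max_per_kidney=float(per_kidney.max()),
        mean_gd=float(gds.mean()),
        sd_gd=float(gds.std(ddof=1)) if n > 1 else 0.0,
        min_gd=float(gds.min()),
        max_gd=float(gds.max()),
        median_gd=float(np.median(gds)),
        median_gd_ci=ci,
    )
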