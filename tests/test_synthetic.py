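"""Generator contracts: determinism, planted-count conservation, geometry,
cohort covariate recovery, and the eligibility filter."""

import math

import numpy as np
import pytest
from scipy.stats import truncnorm

from glomkit.segmentation import CORTEX
from glomkit.synthetic import (
    DEFAULT_EXCLUDED_COUNTS,
    DensityInfeasibleError,
    FEMALE_DEFAULTS,
    MALE_DEFAULTS,
    SlideSpec,
    SubjectRecord,
    bsa_du_bois,
    eligibility_filter,
    generate_cohort,
    generate_slide,
    make_screening_records,
)


class TestGenerateSlide:
    def test_same_seed_is_bit_identical(self):
        spec = SlideSpec(width_px=600, height_px=600, seed=9)
        img1, truth1 = generate_slide(spec)
        img2, truth2 = generate_slide(spec)
        assert img1.pixels.tobytes() == img2.pixels.tobytes()
        assert np.array_equal(truth1.region_mask.labels, truth2.region_mask.labels)
        assert truth1.glomeruli == truth2.glomeruli

    def test_planted_count_conserves_density(self, default_slide):
        _, truth = default_slide
        spec = SlideSpec(seed=42)
        assert truth.n_glomeruli == round(spec.target_gd * truth.cortex_area_mm2)

    def test_zero_density_gives_empty_slide(self):
        img, truth = generate_slide(SlideSpec(width_px=400, height_px=400, target_gd=0.0))
        assert truth.glomeruli == []
        assert (truth.region_mask.labels == CORTEX).any()

    def test_true_area_matches_ellipse_formula(self, default_slide):
        _, truth = default_slide
        for g in truth.glomeruli:
            expected = math.pi * g.axis_a_um * g.axis_b_um
            assert abs(g.area_um2 - expected) / expected < 1e-3

    def test_glomeruli_lie_inside_cortex(self, default_slide):
        _, truth = default_slide
        labels = truth.region_mask.labels
        mpp = truth.region_mask.mpp
        for g in truth.glomeruli:
            row = int(round(g.cy_um / mpp))
            col = int(round(g.cx_um / mpp))
            assert labels[row, col] == CORTEX
            # the whole footprint (tuft + Bowman rim) avoids medulla/background
            r_max = (g.axis_a_um + 10.0) / mpp
            for phi in np.linspace(0, 2 * math.pi, 12, endpoint=False):
                rr = int(round(row + r_max * math.sin(phi)))
                cc = int(round(col + r_max * math.cos(phi)))
                assert labels[rr, cc] == CORTEX

    def test_minimum_spacing_between_centers(self, default_slide):
        _, truth = default_slide
        pts = np.array([(g.cx_um, g.cy_um) for g in truth.glomeruli])
        spec = SlideSpec(seed=42)
        min_spacing = 1.5 * 2.0 * math.sqrt(spec.area_mean / math.pi)
        d = np.hypot(
            pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= min_spacing

    def test_infeasible_density_raises(self):
        spec = SlideSpec(width_px=256, height_px=256, target_gd=400.0)
        with pytest.raises(DensityInfeasibleError, match="density infeasible"):
            generate_slide(spec)

    @pytest.mark.parametrize("bad", [
        dict(cortex_fraction=0.0),
        dict(target_gd=-1.0),
        dict(stain_level="medium"),
        dict(mpp=0.0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_slide(SlideSpec(width_px=256, height_px=256, **bad))

    def test_ground_truth_identical_across_resolutions(self):
        """Same seed → same physical glomeruli whether rasterized at 1 or 2 µm/px."""
        t2 = generate_slide(SlideSpec(width_px=600, height_px=600, mpp=2.0, seed=3))[1]
        t1 = generate_slide(SlideSpec(width_px=1200, height_px=1200, mpp=1.0, seed=3))[1]
        assert t1.n_glomeruli == t2.n_glomeruli
        assert np.allclose(
            [g.cx_um for g in t1.glomeruli], [g.cx_um for g in t2.glomeruli]
        )
        assert t1.cortex_area_mm2 == pytest.approx(t2.cortex_area_mm2)


class TestGenerateCohort:
    def test_default_sizes(self):
        cohort = generate_cohort(seed=0)
        assert sum(r.sex == "male" for r in cohort) == 54
        assert sum(r.sex == "female" for r in cohort) == 32

    def test_single_female_record_is_valid(self):
        (rec,) = generate_cohort(n_male=0, n_female=1, seed=1)
        assert rec.sex == "female"
        assert rec.bmi == pytest.approx(rec.weight_kg / (rec.height_cm / 100) ** 2)
        assert rec.bsa_m2 == pytest.approx(bsa_du_bois(rec.height_cm, rec.weight_kg))
        assert rec.slide_left is not None and rec.slide_right is not None
        assert rec.eligible

    def test_male_height_mean_recovers_parameter(self):
        cohort = generate_cohort(n_male=10_000, n_female=0, seed=7)
        heights = np.array([r.height_cm for r in cohort])
        assert abs(heights.mean() - 178.4) < 0.5

    @pytest.mark.parametrize("attr,params", [
        ("age", MALE_DEFAULTS.age),
        ("weight_kg", MALE_DEFAULTS.weight),
        ("height_cm", FEMALE_DEFAULTS.height),
    ])
    def test_covariate_recovery_within_3_se(self, attr, params):
        """Empirical mean/SD match the truncated-normal generator at n = 10,000."""
        mean, sd, lo, hi = params
        sex = ("male", "female")[attr == "height_cm"]
        cohort = generate_cohort(
            n_male=10_000 if sex == "male" else 0,
            n_female=10_000 if sex == "female" else 0,
            seed=11,
        )
        vals = np.array([getattr(r, attr) for r in cohort])
        a, b = (lo - mean) / sd, (hi - mean) / sd
        expected_mean = truncnorm.mean(a, b, loc=mean, scale=sd)
        expected_sd = truncnorm.std(a, b, loc=mean, scale=sd)
        se = expected_sd / math.sqrt(vals.size)
        assert abs(vals.mean() - expected_mean) < 3 * se
        assert abs(vals.std(ddof=1) - expected_sd) < 4 * expected_sd / math.sqrt(vals.size)

    def test_planted_gd_within_observed_range(self):
        cohort = generate_cohort(n_male=20, n_female=20, seed=3)
        for rec in cohort:
            for spec in (rec.slide_left, rec.slide_right):
                assert spec.target_gd > 0


class TestEligibility:
    def test_screening_population_retains_86(self):
        records = make_screening_records(seed=0)
        assert len(records) == 1165
        included, excluded = eligibility_filter(records)
        assert len(included) == 86
        assert sum(len(v) for v in excluded.values()) == 1079
        for reason, n in DEFAULT_EXCLUDED_COUNTS.items():
            assert len(excluded[reason]) == n

    def test_empty_input(self):
        included, excluded = eligibility_filter([])
        assert included == [] and excluded == {}

    def test_single_flag_routes_to_its_reason(self):
        (rec,) = generate_cohort(n_male=1, n_female=0, seed=2)
        rec.exclusion_flags["blood_depletion"] = True
        included, excluded = eligibility_filter([rec])
        assert included == []
        assert list(excluded) == ["blood_depletion"]

    def test_underage_without_flags_is_a_minor(self):
        (rec,) = generate_cohort(n_male=1, n_female=0, seed=2)
        rec.age = 17.0
        _, excluded = eligibility_filter([rec])
        assert list(excluded) == ["minor"]
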