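"""Detector-chain contracts: resolution handling, tissue/region segmentation
accuracy against planted truth, detection floors, and the cleaning filter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glomkit.segmentation import (
    BACKGROUND,
    CORTEX,
    MEDULLA,
    DetectedObject,
    RegionMask,
    SlideImage,
    classify_tissue,
    clean_objects,
    detect_glomeruli,
    segment_cortex_medulla,
    standardize_resolution,
)
from glomkit.synthetic import SlideSpec, generate_slide
from glomkit.validation import match_objects


def _uniform_slide(color, mpp=2.0, size=200):
    px = np.full((size, size, 3), color, dtype=np.uint8)
    return SlideImage(pixels=px, mpp=mpp)


CORTEX_RGB = (226, 158, 178)
TUFT_RGB = (138, 84, 148)


class TestStandardizeResolution:
    def test_factor_two_decimation(self):
        img = _uniform_slide((200, 150, 170), mpp=1.0, size=1000)
        out = standardize_resolution(img, 2.0)
        assert out.shape == (500, 500)
        assert out.mpp == 2.0

    def test_identity_at_target(self):
        img = _uniform_slide((200, 150, 170), mpp=2.0)
        assert standardize_resolution(img, 2.0) is img

    def test_upsampling_rejected(self):
        img = _uniform_slide((200, 150, 170), mpp=4.0)
        with pytest.raises(ValueError, match="coarser than target"):
            standardize_resolution(img, 2.0)

    def test_tissue_area_conserved_by_downsampling(self):
        img, _ = generate_slide(SlideSpec(width_px=1200, height_px=1200, mpp=1.0, seed=8))
        before = classify_tissue(img).sum() * img.mpp**2
        out = standardize_resolution(img, 2.0)
        after = classify_tissue(out).sum() * out.mpp**2
        assert abs(after - before) / before < 0.01


class TestClassifyTissue:
    def test_agreement_with_planted_truth(self, default_slide):
        img, truth = default_slide
        tissue = classify_tissue(img)
        agreement = (tissue == (truth.region_mask.labels > 0)).mean()
        assert agreement >= 0.99

    def test_uniform_white_has_no_tissue(self):
        img = _uniform_slide((246, 246, 244))
        with pytest.warns(UserWarning, match="no tissue"):
            tissue = classify_tissue(img)
        assert tissue.sum() == 0

    def test_deterministic(self, small_slide):
        img, _ = small_slide
        m1 = classify_tissue(img)
        m2 = classify_tissue(img)
        assert np.array_equal(m1, m2)


class TestSegmentCortexMedulla:
    def test_cortex_agreement_with_planted_truth(self, default_slide):
        img, truth = default_slide
        regions = segment_cortex_medulla(img, classify_tissue(img))
        agreement = (
            (regions.labels == CORTEX) == (truth.region_mask.labels == CORTEX)
        ).mean()
        assert agreement >= 0.95

    def test_all_cortex_slide_has_no_medulla(self):
        img, _ = generate_slide(
            SlideSpec(width_px=600, height_px=600, cortex_fraction=1.0, seed=4)
        )
        regions = segment_cortex_medulla(img, classify_tissue(img))
        assert regions.medulla_area_mm2 <= 0.02 * regions.cortex_area_mm2

    def test_cortex_area_within_5_percent(self):
        for seed in (21, 22, 23):
            img, truth = generate_slide(SlideSpec(seed=seed))
            regions = segment_cortex_medulla(img, classify_tissue(img))
            err = abs(regions.cortex_area_mm2 - truth.cortex_area_mm2)
            assert err / truth.cortex_area_mm2 < 0.05

    def test_every_tissue_pixel_gets_exactly_one_label(self, small_slide):
        img, _ = small_slide
        tissue = classify_tissue(img)
        regions = segment_cortex_medulla(img, tissue)
        assert np.array_equal(regions.labels > 0, tissue)


class TestDetectGlomeruli:
    def test_recovers_planted_glomeruli(self, default_slide):
        img, truth = default_slide
        regions = segment_cortex_medulla(img, classify_tissue(img))
        kept, _ = clean_objects(detect_glomeruli(img, regions))
        match = match_objects(kept, truth)
        assert match.n_false_positive == 0
        assert abs(len(kept) - truth.n_glomeruli) <= max(1, 0.05 * truth.n_glomeruli)
        est = np.mean([o.area_um2 for o in kept])
        true = np.mean([g.area_um2 for g in truth.glomeruli])
        assert abs(est - true) / true < 0.05

    def test_object_below_minimum_size_is_discarded(self):
        px = np.full((200, 200, 3), CORTEX_RGB, dtype=np.uint8)
        px[100:103, 100:103] = TUFT_RGB  # 9 px = 36 µm² at 2 µm/px
        img = SlideImage(pixels=px, mpp=2.0)
        regions = RegionMask(labels=np.full((200, 200), CORTEX, np.uint8), mpp=2.0)
        assert detect_glomeruli(img, regions) == []

    def test_small_object_detected_then_cleaned(self):
        px = np.full((200, 200, 3), CORTEX_RGB, dtype=np.uint8)
        px[90:102, 90:102] = TUFT_RGB  # 144 px = 576 µm²: above 40, below 10,000
        img = SlideImage(pixels=px, mpp=2.0)
        regions = RegionMask(labels=np.full((200, 200), CORTEX, np.uint8), mpp=2.0)
        objects = detect_glomeruli(img, regions)
        assert len(objects) == 1
        kept, excluded = clean_objects(objects)
        assert kept == []
        assert excluded[0].exclusion_reason == "below_area_floor"

    def test_medulla_only_slide_yields_nothing(self):
        px = np.full((200, 200, 3), CORTEX_RGB, dtype=np.uint8)
        regions = RegionMask(labels=np.full((200, 200), MEDULLA, np.uint8), mpp=2.0)
        assert detect_glomeruli(SlideImage(pixels=px, mpp=2.0), regions) == []

    def test_counts_and_areas_consistent_across_resolutions(self):
        """Same physical slide rendered at 1 and 2 µm/px: counts within 2%,
        mean areas within 3%."""
        results = {}
        for mpp, px in ((2.0, 800), (1.0, 1600)):
            img, _ = generate_slide(
                SlideSpec(width_px=px, height_px=px, mpp=mpp, seed=6)
            )
            regions = segment_cortex_medulla(img, classify_tissue(img))
            kept, _ = clean_objects(
                detect_glomeruli(img, regions, min_object_um2=40.0)
            )
            results[mpp] = (len(kept), np.mean([o.area_um2 for o in kept]))
        n2, a2 = results[2.0]
        n1, a1 = results[1.0]
        assert abs(n1 - n2) <= max(1, 0.02 * n2)
        assert abs(a1 - a2) / a2 < 0.03


class TestCleanObjects:
    @staticmethod
    def _obj(i, area, reason="none"):
        return DetectedObject(
            object_id=i,
            centroid_um=(0.0, 0.0),
            area_um2=area,
            perimeter_um=100.0,
            excluded=reason != "none",
            exclusion_reason=reason,
        )

    def test_strict_less_than_boundary(self):
        objs = [self._obj(1, 9_999.0), self._obj(2, 10_000.0), self._obj(3, 24_750.0)]
        kept, excluded = clean_objects(objs)
        assert [o.object_id for o in kept] == [2, 3]
        assert [o.object_id for o in excluded] == [1]
        assert excluded[0].exclusion_reason == "below_area_floor"

    def test_empty_input(self):
        assert clean_objects([]) == ([], [])

    def test_prior_exclusions_are_preserved(self):
        objs = [self._obj(1, 20_000.0, reason="outside_cortex")]
        kept, excluded = clean_objects(objs)
        assert kept == []
        assert excluded[0].exclusion_reason == "outside_cortex"

    @given(st.lists(st.floats(min_value=0, max_value=50_000), max_size=60))
    def test_matches_brute_force_filter(self, areas):
        objs = [self._obj(i, a) for i, a in enumerate(areas)]
        kept, excluded = clean_objects(objs)
        assert len(kept) == sum(1 for a in areas if a >= 10_000)
        assert len(kept) + len(excluded) == len(objs)
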