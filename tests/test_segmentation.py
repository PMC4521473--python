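"""Unit and property tests for per-section segmentation and 3-D linking."""

import numpy as np
import pytest

from organoscreen.segmentation import (
    NucleusObject,
    OrganoidObject,
    SectionMask,
    SegmentationParams,
    assign_nuclei,
    boundary_sharpness,
    filter_out_of_focus,
    link_sections_by_overlap,
    segment_section,
    segment_well,
)
from organoscreen.synthetic import OrganoidSpec, render_well_stack

from .conftest import disk_mask


CLEAN = SegmentationParams(smooth_sigma=0.0, sharpness_min=0.0)


def _pixset(mask: SectionMask) -> set:
    return set(map(tuple, mask.pixels))


class TestSegmentSection:
    def test_noise_free_section_recovers_two_organoids_exactly(self, clean_well):
        stack, truth = clean_well
        section = 3
        masks = segment_section(stack.actin[section], "actin", CLEAN)
        assert len(masks) == 3
        found = {frozenset(_pixset(m)) for m in masks}
        expected = set()
        for oid in (1, 2, 3):
            ys, xs = np.nonzero(truth.labels[section] == oid)
            expected.add(frozenset(zip(xs.tolist(), ys.tolist())))
        assert found == expected

    def test_blank_section_yields_nothing(self):
        assert segment_section(np.zeros((64, 64)), "actin") == []

    def test_min_area_filter(self):
        img = np.zeros((32, 32))
        img[10, 10:13] = 1000.0  # one object of area 3
        params = SegmentationParams(min_object_area=5, smooth_sigma=0.0)
        assert segment_section(img, "actin", params) == []
        params = SegmentationParams(min_object_area=3, smooth_sigma=0.0)
        assert len(segment_section(img, "actin", params)) == 1

    def test_non_finite_intensities_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            segment_section(img)

    def test_nuclei_watershed_splits_touching_blobs(self):
        yy, xx = np.mgrid[0:60, 0:60]
        img = 3000 * np.exp(-((xx - 25) ** 2 + (yy - 30) ** 2) / 18.0)
        img += 3000 * np.exp(-((xx - 35) ** 2 + (yy - 30) ** 2) / 18.0)
        masks = segment_section(img + 100, "nuclei", SegmentationParams())
        assert len(masks) == 2

    def test_raising_min_area_never_increases_mask_count(self, noisy_well):
        stack, _ = noisy_well
        counts = []
        for area in (5, 25, 100, 400):
            params = SegmentationParams(min_object_area=area)
            counts.append(len(segment_section(stack.actin[3], "actin", params)))
        assert counts == sorted(counts, reverse=True)


class TestFocusFilter:
    def test_defocused_sections_are_discarded(self):
        specs = [OrganoidSpec(center=(50.0, 50.0, 2.5), radius=14,
                              nuclei_count=4, z_halfspan=2.5)]
        stack, _ = render_well_stack(specs, (6, 100, 100), noise_sd=60.0,
                                     defocus_sections=(0, 5), seed=8,
                                     psf_sigma=0.8)
        params = SegmentationParams()
        masks = {i: segment_section(stack.actin[i], "actin", params)
                 for i in range(6)}
        kept = filter_out_of_focus(masks, stack.actin, params.sharpness_min)
        assert all(len(kept[i]) == 0 for i in (0, 5) if masks[i])
        assert all(len(kept[i]) == 1 for i in (1, 2, 3, 4))

    def test_zero_threshold_is_identity(self, noisy_well):
        stack, _ = noisy_well
        masks = {i: segment_section(stack.actin[i], "actin")
                 for i in range(stack.actin.shape[0])}
        kept = filter_out_of_focus(masks, stack.actin, 0.0)
        assert {i: len(v) for i, v in kept.items()} == \
               {i: len(v) for i, v in masks.items()}

    def test_infinite_threshold_discards_everything(self, noisy_well):
        stack, _ = noisy_well
        masks = {i: segment_section(stack.actin[i], "actin")
                 for i in range(stack.actin.shape[0])}
        kept = filter_out_of_focus(masks, stack.actin, np.inf)
        assert all(len(v) == 0 for v in kept.values())

    def test_sharpness_score_drops_under_blur(self, clean_well):
        from scipy import ndimage
        stack, _ = clean_well
        mask = segment_section(stack.actin[3], "actin", CLEAN)[0]
        sharp = boundary_sharpness(mask, stack.actin[3])
        blurred = ndimage.gaussian_filter(stack.actin[3].astype(float), 4.0)
        assert boundary_sharpness(mask, blurred) < sharp / 2


class TestOverlapLinking:
    def test_identical_masks_link_into_one_object(self):
        m = disk_mask(5, (10, 10))
        objs = link_sections_by_overlap(
            {0: [SectionMask(0, m.pixels)], 1: [SectionMask(1, m.pixels)]},
            min_overlap_ratio=0.5, width=32)
        assert len(objs) == 1
        assert objs[0].section_indices == [0, 1]

    def test_disjoint_masks_stay_separate(self):
        objs = link_sections_by_overlap(
            {0: [disk_mask(4, (8, 8))], 1: [disk_mask(4, (24, 24))]},
            min_overlap_ratio=0.5, width=32)
        assert len(objs) == 2

    @pytest.mark.parametrize("threshold,linked", [(0.5, True), (0.6, True),
                                                  (0.61, False)])
    def test_overlap_ratio_uses_smaller_mask(self, threshold, linked):
        # A: 100 px, B: 50 px, intersection 30 px -> ratio 30/50 = 0.6
        a = [(x, y) for x in range(10) for y in range(10)]
        b = [(x, y) for x in range(7, 12) for y in range(4)]  # 20 in, 30 out
        b = [(x, y) for x in range(4, 14) for y in range(5)]  # 30 in A, 20 out
        inter = len(set(a) & set(b))
        assert (len(a), len(b), inter) == (100, 50, 30)
        objs = link_sections_by_overlap(
            {0: [SectionMask(0, np.array(a))], 1: [SectionMask(1, np.array(b))]},
            min_overlap_ratio=threshold, width=20)
        assert (len(objs) == 1) is linked

    def test_partition_invariant(self, noisy_well):
        stack, _ = noisy_well
        masks = {i: segment_section(stack.actin[i], "actin")
                 for i in range(stack.actin.shape[0])}
        n_masks = sum(len(v) for v in masks.values())
        objs = link_sections_by_overlap(masks, 0.5, width=stack.actin.shape[2])
        assert sum(len(o.sections) for o in objs) == n_masks

    def test_raising_threshold_never_decreases_object_count(self, noisy_well):
        stack, _ = noisy_well
        masks = {i: segment_section(stack.actin[i], "actin")
                 for i in range(stack.actin.shape[0])}
        counts = []
        for thr in (0.1, 0.3, 0.5, 0.8, 1.01):
            objs = link_sections_by_overlap(
                {i: [SectionMask(m.section_index, m.pixels, m.channel)
                     for m in v] for i, v in masks.items()},
                thr, width=stack.actin.shape[2])
            counts.append(len(objs))
        assert counts == sorted(counts)


class TestAssignNuclei:
    def _one_organoid(self):
        return [OrganoidObject(object_id=1, sections=[disk_mask(6, (10, 10))])]

    def test_center_inside_mask_is_assigned(self):
        orgs = self._one_organoid()
        nuc = NucleusObject(0, (10.0, 10.0), 4)
        left = assign_nuclei(orgs, [nuc], max_dist=5)
        assert left == [] and orgs[0].children == [nuc]

    @pytest.mark.parametrize("max_dist,assigned", [(5.0, True), (2.0, False)])
    def test_outside_mask_uses_distance_tolerance(self, max_dist, assigned):
        orgs = self._one_organoid()
        nuc = NucleusObject(0, (19.0, 10.0), 4)  # 3 px right of the rim pixel
        assign_nuclei(orgs, [nuc], max_dist=max_dist)
        assert (nuc in orgs[0].children) is assigned

    def test_clean_well_parentage_matches_ground_truth(self, clean_well):
        stack, truth = clean_well
        organoids, _nuc_objs, nuclei = segment_well(
            stack.actin, stack.nuclei,
            SegmentationParams(smooth_sigma=0.0, sharpness_min=0.0))
        assert len(organoids) == truth.n_objects
        # every detected nucleus is assigned, and to the correct parent:
        # its nearest ground-truth nucleus belongs to the organoid whose
        # label region the segmented parent occupies
        assert sum(len(o.children) for o in organoids) == len(nuclei)
        for org in organoids:
            m = org.sections[0]
            cx, cy = m.centroid
            true_id = truth.labels[m.section_index, int(round(cy)), int(round(cx))]
            assert org.children  # nuclei found for every organoid
            for child in org.children:
                gx, gy = child.mass_center
                nearest = min(truth.nuclei,
                              key=lambda n: (n.x - gx) ** 2 + (n.y - gy) ** 2)
                assert nearest.object_id == true_id
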