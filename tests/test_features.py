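"""Unit tests for the canonical morphology statistics and the well battery."""

import math

import numpy as np
import pandas as pd
import pytest

from organoscreen.features import (
    CANONICAL_FEATURES,
    N_FEATURES,
    cell_polarity,
    extract_feature_battery,
    feature_definitions,
    feature_names,
    invasion_inhibition,
    max_pairwise_distance,
    organoid_branching,
    organoid_count,
    per_organoid_size,
    skeleton_branch_lengths,
    total_proliferation,
    zscore_normalize,
)
from organoscreen.segmentation import NucleusObject, OrganoidObject, SectionMask, segment_well

from .conftest import disk_mask, mask_from_pixels
from .oracles import brute_cell_polarity, brute_max_pairwise


class TestInvasionInhibition:
    def test_pixel_row_matches_printed_formula(self):
        # 1x9 row: area 9, max distance 8 -> 36/(64 pi)
        mask = mask_from_pixels([(x, 0) for x in range(9)])
        assert invasion_inhibition(mask) == pytest.approx(36 / (64 * math.pi))

    def test_digital_disk_is_close_to_one(self):
        val = invasion_inhibition(disk_mask(20))
        assert 0.95 <= val <= 1.10

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError):
            invasion_inhibition(mask_from_pixels([(0, 0)]))

    def test_dilation_invariance_within_discretisation(self):
        # scale-free statistic: integer dilation changes it by <= 5 %
        base = disk_mask(15)
        scaled = mask_from_pixels(
            [(x, y) for bx, by in base.pixels
             for x in (2 * bx, 2 * bx + 1)
             for y in (2 * by, 2 * by + 1)])
        a, b = invasion_inhibition(base), invasion_inhibition(scaled)
        assert abs(a - b) / a <= 0.05
        # while the area scales with the square of the dilation factor
        assert per_organoid_size(scaled) == 4 * per_organoid_size(base)

    def test_max_pairwise_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 40, size=(60, 2))
        pts = np.unique(pts, axis=0)
        assert max_pairwise_distance(pts) == pytest.approx(
            brute_max_pairwise(pts), abs=1e-12)


class TestSizeAndProliferation:
    def test_square_and_pixel(self):
        square = mask_from_pixels([(x, y) for x in range(3) for y in range(3)])
        assert per_organoid_size(square) == 9
        assert per_organoid_size(mask_from_pixels([(5, 5)])) == 1

    def test_disk_equals_brute_count(self):
        r = 10
        xs, ys = np.mgrid[-12:13, -12:13]
        expected = int((xs**2 + ys**2 <= r * r).sum())
        assert per_organoid_size(disk_mask(r)) == expected

    def test_total_proliferation_accumulates_sections(self):
        # organoids of areas 5 and 7 present identically in 3 sections
        m5 = [(x, 0) for x in range(5)]
        m7 = [(x, 2) for x in range(7)]
        masks = [mask_from_pixels(m) for m in (m5, m7)] * 3
        assert total_proliferation(masks) == 36
        assert total_proliferation([]) == 0
        assert total_proliferation(masks) == sum(per_organoid_size(m) for m in masks)


class TestCellPolarity:
    def _organoid_with_nucleus(self, mask, center):
        org = OrganoidObject(object_id=1, sections=[mask])
        org.children = [NucleusObject(section_index=0, mass_center=center, area=5)]
        return org

    def test_centered_nucleus_in_disk(self):
        mask = disk_mask(10, center=(15, 15))
        mean, sd = cell_polarity(self._organoid_with_nucleus(mask, (15.0, 15.0)), 0)
        bmean, bsd = brute_cell_polarity(np.array([[15.0, 15.0]]), mask.pixels)
        assert mean == pytest.approx(bmean, abs=1e-12)
        assert 8.5 <= mean <= 10.0  # nearest boundary-pixel center of an r=10 disk
        assert sd == 0.0

    def test_nucleus_on_boundary_scores_zero(self):
        mask = disk_mask(10, center=(15, 15))
        bx, by = mask.pixels[np.argmax(mask.pixels[:, 0])]  # rightmost pixel
        mean, _ = cell_polarity(
            self._organoid_with_nucleus(mask, (float(bx), float(by))), 0)
        assert mean == 0.0

    def test_hollow_boundary_placement_scores_lower_than_scattered(self):
        mask = disk_mask(12, center=(20, 20))
        rng = np.random.default_rng(5)
        ring = OrganoidObject(object_id=1, sections=[mask])
        angles = rng.uniform(0, 2 * math.pi, 6)
        ring.children = [
            NucleusObject(0, (20 + 10.5 * math.cos(a), 20 + 10.5 * math.sin(a)), 5)
            for a in angles
        ]
        solid = OrganoidObject(object_id=2, sections=[mask])
        rr = 11 * np.sqrt(rng.uniform(0, 1, 6))
        aa = rng.uniform(0, 2 * math.pi, 6)
        solid.children = [
            NucleusObject(0, (20 + r * math.cos(a), 20 + r * math.sin(a)), 5)
            for r, a in zip(rr, aa)
        ]
        ring_mean, ring_sd = cell_polarity(ring, 0)
        solid_mean, solid_sd = cell_polarity(solid, 0)
        assert ring_mean < solid_mean
        assert ring_sd < solid_sd

    def test_no_nuclei_in_section_is_undefined(self):
        org = OrganoidObject(object_id=1, sections=[disk_mask(5, (8, 8))])
        with pytest.raises(ValueError):
            cell_polarity(org, 0)


class TestBranching:
    def test_plus_shape_mean_is_arm_length(self):
        L = 7
        pixels = [(0, 0)]
        pixels += [(x, 0) for x in range(1, L + 1)]
        pixels += [(-x, 0) for x in range(1, L + 1)]
        pixels += [(0, y) for y in range(1, L + 1)]
        pixels += [(0, -y) for y in range(1, L + 1)]
        mask = mask_from_pixels([(x + 10, y + 10) for x, y in pixels])
        lengths = skeleton_branch_lengths(mask)
        # hand enumeration: skeletonisation trims the open tip of each
        # one-pixel-wide arm, leaving four equal branches of length L - 1
        assert len(lengths) == 4
        assert set(lengths) == {L - 1}
        assert organoid_branching(mask) == pytest.approx(L - 1)

    def test_compact_disk_has_no_branches(self):
        assert organoid_branching(disk_mask(6, (8, 8))) == 0.0

    def test_t_shape_mean_of_three_arms(self):
        # T: horizontal bar of 2L+1 pixels with a vertical stem of length L
        L = 6
        pixels = [(x, 0) for x in range(-L, L + 1)]
        pixels += [(0, y) for y in range(1, L + 1)]
        mask = mask_from_pixels([(x + 10, y + 10) for x, y in pixels])
        lengths = sorted(skeleton_branch_lengths(mask))
        # three arms of hand-enumerated skeleton length L - 1 (trimmed tips)
        assert lengths == [L - 1] * 3
        assert organoid_branching(mask) == pytest.approx(L - 1)


class TestOrganoidCount:
    def _objects(self, spans):
        objs = []
        for oid, n_sections in enumerate(spans, 1):
            masks = [SectionMask(i, np.array([[oid * 3, i]])) for i in range(n_sections)]
            objs.append(OrganoidObject(object_id=oid, sections=masks))
        return objs

    def test_printed_per_section_sum(self):
        assert organoid_count(self._objects([3, 3])) == 6
        assert organoid_count([]) == 0
        assert organoid_count(self._objects([1])) == 1

    def test_distinct_objects_variant(self):
        assert organoid_count(self._objects([3, 3]), "distinct_objects") == 2

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            organoid_count([], "volume")


class TestBattery:
    def test_vector_length_and_names(self, noisy_well):
        stack, _ = noisy_well
        org, nuc, _ = segment_well(stack.actin, stack.nuclei)
        vec = extract_feature_battery(org, nuc, stack.actin.astype(float),
                                      stack.nuclei.astype(float))
        assert len(vec) == N_FEATURES == 294
        assert list(vec.index) == feature_names()
        assert set(CANONICAL_FEATURES) <= set(vec.index)

    def test_every_base_feature_is_documented(self):
        defs = feature_definitions()
        bases = {n.rsplit("__", 1)[0].split("_", 1)[1] for n in feature_names()}
        assert bases <= set(defs)

    def test_single_organoid_well_has_zero_sd_aggregates(self):
        mask = disk_mask(9, (20, 20))
        org = OrganoidObject(object_id=1, sections=[mask])
        org.children = [NucleusObject(0, (20.0, 20.0), 6)]
        nuc = OrganoidObject(object_id=1, sections=[SectionMask(0, np.array([[20, 20], [21, 20], [20, 21], [21, 21]]), "nuclei")])
        img = np.full((1, 48, 48), 400.0)
        img[0][mask.to_image((48, 48))] = 9000.0
        vec = extract_feature_battery([org], [nuc], img, img * 0.5 + 200)
        sd_cols = [c for c in vec.index if c.endswith("__sd")]
        assert (vec[sd_cols].fillna(0) == 0).all()

    def test_determinism_identical_specs_and_seed(self, clean_well):
        stack, _ = clean_well
        out = []
        for _ in range(2):
            org, nuc, _ = segment_well(stack.actin, stack.nuclei)
            out.append(extract_feature_battery(
                org, nuc, stack.actin.astype(float), stack.nuclei.astype(float)))
        pd.testing.assert_series_equal(out[0], out[1])


class TestZScoreNormalize:
    def _table(self, buffer_values, treated_values, feature="f"):
        rows = {f"B{i}": v for i, v in enumerate(buffer_values)}
        rows.update({f"T{i}": v for i, v in enumerate(treated_values)})
        table = pd.DataFrame({feature: rows})
        pm = pd.DataFrame({
            "well": list(rows),
            "role": ["buffer"] * len(buffer_values) + ["treatment"] * len(treated_values),
        })
        return table, pm

    def test_three_buffer_values_normalise_to_unit_steps(self):
        table, pm = self._table([1.0, 2.0, 3.0], [4.0])
        norm, excluded = zscore_normalize(table, pm)
        assert excluded == []
        assert list(norm.loc[["B0", "B1", "B2"], "f"]) == pytest.approx([-1, 0, 1])

    def test_buffer_mean_zero_sd_one(self, noisy_well):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(5, 2, size=(12, 4)),
                             index=[f"W{i}" for i in range(12)],
                             columns=list("abcd"))
        pm = pd.DataFrame({"well": table.index,
                           "role": ["buffer"] * 6 + ["treatment"] * 6})
        norm, _ = zscore_normalize(table, pm)
        buf = norm.iloc[:6]
        assert np.allclose(buf.mean(), 0, atol=1e-12)
        assert np.allclose(buf.std(ddof=1), 1, atol=1e-12)

    def test_constant_buffer_feature_excluded_not_nan(self):
        table, pm = self._table([2.0, 2.0, 2.0], [5.0])
        norm, excluded = zscore_normalize(table, pm)
        assert excluded == ["f"]
        assert "f" not in norm.columns

    def test_requires_two_buffer_wells(self):
        table, pm = self._table([1.0], [2.0])
        with pytest.raises(ValueError):
            zscore_normalize(table, pm)
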