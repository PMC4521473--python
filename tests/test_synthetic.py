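"""Unit and property tests for the synthetic microtissue generator."""

import numpy as np
import pytest
from scipy import stats

from organoscreen.features import max_pairwise_distance, skeleton_branch_lengths
from organoscreen.segmentation import SectionMask
from organoscreen.synthetic import (
    OrganoidSpec,
    PlateSpec,
    TreatmentSpec,
    build_plate_map,
    default_class_templates,
    generate_plate,
    invasive_template,
    null_template,
    render_well_stack,
    simulate_feature_table,
)


def small_plate(template, seed=0, doses=(1.0, 3.0, 30.0), replicates=2, n_treat=2):
    treatments = tuple(
        TreatmentSpec(name=f"t{i}", template=template, doses=doses,
                      replicates=replicates)
        for i in range(n_treat)
    )
    return PlateSpec(treatments=treatments, seed=seed, geometry=(6, 220, 220),
                     noise_sd=120.0, defocus_sections=())


class TestRenderWellStack:
    def test_noise_free_half_max_threshold_recovers_ground_truth(self):
        spec = OrganoidSpec(center=(40.0, 40.0, 2.0), radius=12,
                            nuclei_count=4, z_halfspan=1.5)
        stack, truth = render_well_stack([spec], (5, 80, 80), noise_sd=0.0, seed=3)
        half_max = (int(stack.actin.max()) + int(stack.actin.min())) / 2
        recovered = stack.actin > half_max
        assert np.array_equal(recovered, truth.labels > 0)

    def test_hollow_lumen_stays_above_half_max(self):
        spec = OrganoidSpec(center=(40.0, 40.0, 2.0), radius=12, hollow=True,
                            nuclei_count=4, z_halfspan=1.5)
        stack, truth = render_well_stack([spec], (5, 80, 80), noise_sd=0.0, seed=3)
        half_max = (int(stack.actin.max()) + int(stack.actin.min())) / 2
        assert np.array_equal(stack.actin > half_max, truth.labels > 0)

    def test_identical_inputs_and_seed_are_byte_identical(self):
        specs = [OrganoidSpec(center=(50.0, 50.0, 2.0), radius=10,
                              n_branches=2, nuclei_count=5, z_halfspan=1.5)]
        a, _ = render_well_stack(specs, (5, 100, 100), noise_sd=80.0, seed=7,
                                 psf_sigma=1.0)
        b, _ = render_well_stack(specs, (5, 100, 100), noise_sd=80.0, seed=7,
                                 psf_sigma=1.0)
        assert a.actin.tobytes() == b.actin.tobytes()
        assert a.nuclei.tobytes() == b.nuclei.tobytes()

    def test_ground_truth_bookkeeping(self):
        specs = [
            OrganoidSpec(center=(c, c, 2.0), radius=9, nuclei_count=5,
                         z_halfspan=1.5)
            for c in (35.0, 90.0, 145.0)
        ]
        _, truth = render_well_stack(specs, (5, 180, 180), noise_sd=0.0, seed=1)
        assert truth.n_objects == 3
        assert len(truth.nuclei) == 15
        assert {n.object_id for n in truth.nuclei} == {1, 2, 3}
        # exclusive voxel ownership
        assert set(np.unique(truth.labels)) <= {0, 1, 2, 3}

    def test_out_of_canvas_spec_is_rejected_with_index(self):
        specs = [OrganoidSpec(center=(50.0, 50.0, 2.0), radius=10, z_halfspan=1.5),
                 OrganoidSpec(center=(98.0, 50.0, 2.0), radius=10, z_halfspan=1.5)]
        with pytest.raises(ValueError, match="#1"):
            render_well_stack(specs, (5, 100, 100))

    def test_nuclei_mass_centers_match_rendered_blobs(self):
        spec = OrganoidSpec(center=(40.0, 40.0, 2.0), radius=12,
                            nuclei_count=1, z_halfspan=1.5)
        stack, truth = render_well_stack([spec], (5, 80, 80), noise_sd=0.0, seed=5)
        rec = truth.nuclei[0]
        img = stack.nuclei[rec.section].astype(float)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert abs(peak[1] - rec.x) <= 1 and abs(peak[0] - rec.y) <= 1


class TestDialMonotonicity:
    def test_elongation_increases_footprint_major_axis(self):
        axes = []
        for e in (1.0, 1.5, 2.0):
            spec = OrganoidSpec(center=(60.0, 60.0, 1.0), radius=10,
                                elongation=e, z_halfspan=1.0)
            _, truth = render_well_stack([spec], (3, 120, 120), seed=2)
            ys, xs = np.nonzero(truth.labels[1])
            axes.append(max_pairwise_distance(np.column_stack([xs, ys])))
        assert axes[0] < axes[1] < axes[2]

    def test_branch_dial_increases_skeleton_branch_count(self):
        counts = []
        for n in (0, 2, 5):
            spec = OrganoidSpec(center=(60.0, 60.0, 1.0), radius=10,
                                n_branches=n, branch_length=14, z_halfspan=1.0,
                                branch_angles=tuple(np.linspace(0, 5.5, max(n, 1))))
            _, truth = render_well_stack([spec], (3, 120, 120), seed=2)
            ys, xs = np.nonzero(truth.labels[1])
            counts.append(len(skeleton_branch_lengths(
                SectionMask(1, np.column_stack([xs, ys])))))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]


class TestGeneratePlate:
    def test_buffer_fraction_gives_expected_buffer_wells(self):
        plate = small_plate(null_template())  # 12 treatment wells
        assert plate.n_wells == 16
        assert plate.n_buffer_wells == 4
        pm = build_plate_map(plate)
        assert (pm["role"] == "buffer").sum() == 4
        assert len(pm) == 16

    def test_non_integer_buffer_fraction_rejected(self):
        with pytest.raises(ValueError):
            PlateSpec(treatments=(TreatmentSpec(name="t", template=null_template(),
                                                doses=(1.0,), replicates=5),),
                      buffer_fraction=0.25)

    def test_zero_slope_template_matches_buffer_statistically(self):
        plate = small_plate(null_template(), seed=4)
        _stacks, truths, pm = generate_plate(plate)
        pm = pm.set_index("well")
        dials = {}
        for well, truth in truths.items():
            radii = [s.radius for s in truth.specs]
            arms = [s.n_branches for s in truth.specs]
            dials[well] = (len(truth.specs), float(np.mean(radii)), float(np.mean(arms)))
        buf = np.array([dials[w] for w in pm.index[pm.role == "buffer"]])
        trt = np.array([dials[w] for w in pm.index[pm.role == "treatment"]])
        # no dial separates treatment from buffer at Bonferroni-corrected alpha
        for j in range(buf.shape[1]):
            p = stats.mannwhitneyu(buf[:, j], trt[:, j]).pvalue
            assert p > 0.05 / 3

    def test_invasive_template_top_dose_lengthens_protrusions(self):
        plate = small_plate(invasive_template(), seed=4)
        _stacks, truths, pm = generate_plate(plate)
        pm = pm.set_index("well")
        arm_len = {
            w: float(np.mean([s.branch_length for s in t.specs]))
            for w, t in truths.items()
        }
        top = pm.index[(pm.role == "treatment") & (pm.dose == 30.0)]
        buf = pm.index[pm.role == "buffer"]
        assert np.mean([arm_len[w] for w in top]) > np.mean([arm_len[w] for w in buf])

    def test_plate_is_deterministic_in_seed(self):
        plate = small_plate(invasive_template(), seed=9, n_treat=2)
        s1, _, _ = generate_plate(plate)
        s2, _, _ = generate_plate(plate)
        w = next(iter(s1))
        assert s1[w].actin.tobytes() == s2[w].actin.tobytes()


class TestSimulateFeatureTable:
    def test_two_templates_are_linearly_separable_on_the_planted_feature(self):
        table, labels = simulate_feature_table(
            {"lo": np.array([-5.0, 0, 0, 0, 0, 0]),
             "hi": np.array([5.0, 0, 0, 0, 0, 0])},
            n_per_class=20, n_noise_features=50, seed=0)
        col = table.columns[0]
        predicted = np.where(table[col] > 0, "hi", "lo")
        assert (predicted == labels.to_numpy()).all()

    def test_pure_noise_column_means_bounded(self):
        table, _ = simulate_feature_table(
            [np.zeros(6), np.zeros(6)], n_per_class=50,
            n_noise_features=294, seed=1)
        bound = 4 / np.sqrt(len(table))
        noise_cols = [c for c in table.columns if c.startswith("noise")]
        assert (table[noise_cols].mean().abs() < bound).all()

    def test_identical_seed_identical_table(self):
        kwargs = dict(n_per_class=5, n_noise_features=10, seed=42)
        t1, _ = simulate_feature_table(default_class_templates(), **kwargs)
        t2, _ = simulate_feature_table(default_class_templates(), **kwargs)
        assert t1.equals(t2)

    def test_fewer_than_two_templates_rejected(self):
        with pytest.raises(ValueError):
            simulate_feature_table([np.zeros(6)], n_per_class=5)

    def test_default_class_templates_are_well_separated(self):
        cents = list(default_class_templates().values())
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                assert np.linalg.norm(cents[i] - cents[j]) >= 4.0
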