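import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoscreen.plates import WellAddress
from phytoscreen.roots import (
    OrientationMap,
    SegmentationConfig,
    analyze_side_well,
    compute_root_traits,
    crop_wells,
    estimate_orientation,
    partition_quadrants,
    segment_roots,
    traits_from_truth,
)
from phytoscreen.simulate import (
    RootSystem,
    Segment,
    WellGeometry,
    phenotype_preset,
    render_side_view,
    render_strip,
    simulate_root_system,
)


def _bar_render(theta_deg, length=60.0, width=2.5, size=100):
    theta = math.radians(theta_deg)
    half = length / 2.0
    c = (size - 1) / 2.0
    p0 = [c - half * math.sin(theta), c - half * math.cos(theta)]
    p1 = [c + half * math.sin(theta), c + half * math.cos(theta)]
    geom = WellGeometry(height_px=size, width_px=size)
    system = RootSystem([Segment(np.array([p0, p1]), "lateral", width)], geom)
    return render_side_view(system, noise_sd=0.0)


class TestCropWells:
    def test_crops_equal_composited_wells(self, small_geometry):
        wells = [
            render_side_view(
                simulate_root_system(
                    phenotype_preset("control", days=3.0), small_geometry, seed=s
                ),
                noise_sd=0.0,
            )
            for s in range(4)
        ]
        strip, boxes = render_strip(wells)
        addr = WellAddress(plate_id="A1", strip_index=3, view="Side")
        crops = crop_wells(strip, boxes, addr)
        assert [a.well_index for a, _ in crops] == [1, 2, 3, 4]
        for (well_addr, crop), well in zip(crops, wells):
            assert np.array_equal(crop, well.image)
            assert well_addr.strip_index == 3

    def test_overlapping_boxes_warn_but_run(self):
        image = np.zeros((20, 40, 3))
        with pytest.warns(UserWarning, match="overlap"):
            crops = crop_wells(image, [(0, 0, 20, 25), (0, 20, 20, 40)])
        assert len(crops) == 2

    def test_box_outside_image_raises(self):
        image = np.zeros((20, 40, 3))
        with pytest.raises(ValueError, match="outside image"):
            crop_wells(image, [(0, 30, 20, 50)])


class TestSegmentRoots:
    def test_noise_only_false_positive_budget(self):
        """Across 100 noise-only renders the map sums below 0.5% of pixels."""
        geom = WellGeometry(height_px=120, width_px=40)
        empty = RootSystem([], geom)
        budget = 0.005 * geom.height_px * geom.width_px
        for seed in range(100):
            rendered = render_side_view(empty, noise_sd=0.02, seed=seed)
            assert segment_roots(rendered.image).sum() < budget

    def test_recovers_truth_mass_on_noise_free_render(self, control_well):
        prob = segment_roots(control_well.image)
        truth = control_well.truth_probability.sum()
        assert prob.sum() == pytest.approx(truth, rel=0.10)

    def test_values_clamped_to_unit_interval(self, noisy_control_well):
        prob = segment_roots(noisy_control_well.image)
        assert prob.min() >= 0.0 and prob.max() <= 1.0
        flat = np.ones((50, 50, 3))
        assert segment_roots(flat).max() <= 1.0

    def test_uint8_input_equivalent_to_float(self, control_well):
        as_uint8 = (control_well.image * 255 + 0.5).astype(np.uint8)
        a = segment_roots(control_well.image)
        b = segment_roots(as_uint8)
        assert a.sum() == pytest.approx(b.sum(), rel=0.02)


class TestEstimateOrientation:
    @pytest.mark.parametrize("theta", [0, 45, 90])
    def test_straight_bar_recovered_within_3_degrees(self, theta):
        rendered = _bar_render(theta)
        prob = segment_roots(rendered.image)
        orient = estimate_orientation(prob, rendered.image)
        mask = orient.valid & (prob > 0.2)
        mean = np.average(orient.angle_deg[mask], weights=prob[mask])
        assert mean == pytest.approx(theta, abs=3.0)

    def test_mirrored_bar_same_folded_statistics(self):
        rendered = _bar_render(30)
        mirrored_img = rendered.image[:, ::-1].copy()
        prob_a = segment_roots(rendered.image)
        prob_b = segment_roots(mirrored_img)
        a = estimate_orientation(prob_a, rendered.image)
        b = estimate_orientation(prob_b, mirrored_img)
        mean_a = np.average(a.angle_deg[a.valid], weights=prob_a[a.valid])
        mean_b = np.average(b.angle_deg[b.valid], weights=prob_b[b.valid])
        assert mean_a == pytest.approx(mean_b, abs=1.0)

    def test_shape_mismatch_rejected(self, control_well):
        with pytest.raises(ValueError, match="differ"):
            estimate_orientation(np.zeros((10, 10)), control_well.image)

    def test_angles_stay_in_fold_range(self, control_well):
        prob = segment_roots(control_well.image)
        orient = estimate_orientation(prob, control_well.image)
        angles = orient.angle_deg[orient.valid]
        assert angles.min() >= 0.0 and angles.max() <= 90.0


class TestQuadrantBands:
    def test_exact_division(self):
        bands = partition_quadrants(400)
        assert bands.bands == [(0, 100), (100, 200), (200, 300), (300, 400)]

    def test_remainder_rows_go_to_top(self):
        assert partition_quadrants(402).heights == (101, 101, 100, 100)
        assert partition_quadrants(403).heights == (101, 101, 101, 100)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            partition_quadrants(3)

    @settings(derandomize=True, max_examples=60)
    @given(n=st.integers(4, 5000))
    def test_partition_covers_all_rows(self, n):
        bands = partition_quadrants(n)
        assert sum(bands.heights) == n
        assert bands.edges[0] == 0 and bands.edges[-1] == n
        assert max(bands.heights) - min(bands.heights) <= 1


class TestComputeRootTraits:
    def test_all_zero_map_gives_zero_traits(self):
        prob = np.zeros((100, 40))
        orient = OrientationMap(np.zeros((100, 40)), np.zeros((100, 40), bool))
        traits = compute_root_traits(prob, orient, partition_quadrants(100))
        assert traits.root_mass == 0.0
        assert traits.q.sum() == 0.0

    def test_horizontal_bar_in_top_band_is_q0_horizontal(self):
        prob = np.zeros((400, 200))
        prob[50, 25:175] = 1.0  # 150 px in band 0
        angle = np.zeros((400, 200))
        valid = prob > 0
        traits = compute_root_traits(
            prob, OrientationMap(angle, valid), partition_quadrants(400)
        )
        assert traits.root_mass == 150.0
        assert traits.q0_horizontal == 150.0
        assert traits.q.sum() == 150.0

    def test_vertical_bar_in_bottom_band_is_q3_vertical(self):
        prob = np.zeros((400, 200))
        prob[310:390, 100] = 1.0  # 80 px in band 3
        angle = np.full((400, 200), 90.0)
        traits = compute_root_traits(
            prob, OrientationMap(angle, prob > 0), partition_quadrants(400)
        )
        assert traits.q3_vertical == 80.0
        assert traits.root_mass == 80.0

    def test_conservation_is_exact(self, noisy_control_well):
        traits = analyze_side_well(noisy_control_well.image)
        assert traits.q.sum() + traits.invalid_mass == traits.root_mass

    def test_invalid_orientation_mass_counts_toward_root_mass_only(self):
        prob = np.full((8, 8), 0.5)
        angle = np.zeros((8, 8))
        valid = np.zeros((8, 8), bool)
        valid[:4] = True
        traits = compute_root_traits(
            prob, OrientationMap(angle, valid), partition_quadrants(8)
        )
        assert traits.q.sum() == pytest.approx(16.0)
        assert traits.invalid_mass == pytest.approx(16.0)
        assert traits.root_mass == pytest.approx(32.0)

    @settings(derandomize=True, max_examples=40)
    @given(angle=st.floats(0.0, 90.0))
    def test_every_angle_falls_in_exactly_one_bin(self, angle):
        prob = np.ones((4, 1))
        angles = np.full((4, 1), angle)
        traits = compute_root_traits(
            prob, OrientationMap(angles, np.ones((4, 1), bool)), partition_quadrants(4)
        )
        assert traits.q.sum() == pytest.approx(4.0)
        assert np.count_nonzero(traits.q.sum(axis=0)) == 1

    def test_dimension_mismatch_rejected(self):
        prob = np.zeros((10, 10))
        orient = OrientationMap(np.zeros((10, 10)), np.zeros((10, 10), bool))
        with pytest.raises(ValueError):
            compute_root_traits(prob, orient, partition_quadrants(8))


class TestOracleEquivalence:
    def test_root_mass_matches_truth_on_control_wells(self):
        geom = WellGeometry()
        for seed in (21, 22):
            system = simulate_root_system(phenotype_preset("control"), geom, seed=seed)
            rendered = render_side_view(system, noise_sd=0.0)
            est = analyze_side_well(rendered.image)
            truth = traits_from_truth(rendered)
            assert est.root_mass == pytest.approx(truth.root_mass, rel=0.10)

    def test_headline_traits_track_truth(self):
        """Q0-horizontal and the dominant vertical bins agree with truth."""
        geom = WellGeometry()
        est_q = np.zeros((4, 4))
        truth_q = np.zeros((4, 4))
        for seed in range(23, 29):
            system = simulate_root_system(phenotype_preset("control"), geom, seed=seed)
            rendered = render_side_view(system, noise_sd=0.0)
            est_q += analyze_side_well(rendered.image).q
            truth_q += traits_from_truth(rendered).q
        assert est_q[0, 0] == pytest.approx(truth_q[0, 0], rel=0.15)
        assert est_q[2, 3] == pytest.approx(truth_q[2, 3], rel=0.15)
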